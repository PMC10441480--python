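import logging

import numpy as np
import pandas as pd
import pytest

from protscreen.aa_encoding import PropertyDictionary, load_property_dictionary
from protscreen.ensemble import (
    DEFAULT_FAMILIES,
    build_stacked_ensemble,
    evaluate,
    predict_ensemble,
    rank_scales,
    run_property_sweep,
)
from protscreen.library_io import (
    BaseConstruct,
    VariantLibrary,
    deduplicate_average,
    parse_variant_table,
    split_train_test,
)
from protscreen.simulate import SyntheticLibraryConfig, simulate_library

logging.getLogger("protscreen").setLevel(logging.ERROR)

TRUE_SCALE = "KYTJ820101"


@pytest.fixture(scope="session")
def dictionary() -> PropertyDictionary:
    return load_property_dictionary()


@pytest.fixture(scope="session")
def dict10(dictionary) -> PropertyDictionary:
    """True scale + 9 decoy scales from the packaged fixture."""
    others = [s for s in dictionary if s.scale_id != TRUE_SCALE][:9]
    return PropertyDictionary([dictionary.get(TRUE_SCALE)] + others)


@pytest.fixture
def tiny_base() -> BaseConstruct:
    return BaseConstruct(name="tiny", sequence="ACDEF")


@pytest.fixture
def small_library(tiny_base) -> VariantLibrary:
    rows = pd.DataFrame(
        {
            "id": ["v1", "v2", "v3", "wt"],
            "mutations": ["D3Y", "A1C;F5W", "E4G", ""],
            "dff": [1.2, 0.8, 2.0, 1.0],
        }
    )
    return parse_variant_table(rows, tiny_base, "dff")


@pytest.fixture(scope="session")
def recovery():
    """One full synthetic parameter-recovery run, shared across tests.

    n=600 single mutants of a 120-residue base at 40 positions; phenotype is
    additive in the hydropathy scale with noise sd = 10% of the effect range
    (effect_size * scale span = 0.5 * 9.0).  Swept over a 10-scale dictionary
    with the default grids.
    """
    full = load_property_dictionary()
    others = [s for s in full if s.scale_id != TRUE_SCALE][:9]
    d10 = PropertyDictionary([full.get(TRUE_SCALE)] + others)
    cfg = SyntheticLibraryConfig(
        true_scale_id=TRUE_SCALE,
        n_variants=600,
        base_length=120,
        n_mutable_positions=40,
        effect_size=0.5,
        intercept=1.0,
        noise_sd=0.1 * 0.5 * 9.0,
        seed=7,
    )
    library = deduplicate_average(simulate_library(cfg, full))
    split = split_train_test(library, 0.8, 42)
    sweep = run_property_sweep(library, split, d10, seed=1, feature_k=100)
    ensemble = build_stacked_ensemble(sweep, library, split, d10, top_n=5, seed=1)
    test_lib = library.subset(split.test_ids)
    records = predict_ensemble(ensemble, test_lib)
    r2, mse = evaluate([r.mean_prediction for r in records], test_lib.target_values())
    rank1 = {fam: rank_scales(sweep, fam)[0].scale_id for fam in DEFAULT_FAMILIES}
    return {
        "library": library,
        "split": split,
        "sweep": sweep,
        "ensemble": ensemble,
        "records": records,
        "test_r2": r2,
        "rank1": rank1,
        "true_scale": TRUE_SCALE,
    }
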