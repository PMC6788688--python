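import numpy as np
import pytest

import crossfsv as cf


@pytest.fixture(scope="session")
def gmap():
    """One 120-cM chromosome at ~1 Mb/cM marker spacing."""
    return cf.build_genetic_map(1, 120, 1.0, seed=3)


@pytest.fixture(scope="session")
def gmap_coarse():
    """Small two-chromosome map for cheap structural tests."""
    return cf.build_genetic_map(2, 30, 2.0, seed=9)


@pytest.fixture(scope="session")
def cross_medium(gmap):
    """Medium cross (400 F2, 12 sire families) with the default 25% QTL."""
    cfg = cf.lk_config(gmap, seed=11, n_f2=400, n_f1=24, n_f0_sires=6, n_f0_dams=6)
    return cf.simulate(cfg, gmap), cfg


@pytest.fixture(scope="session")
def cross_masa(gmap):
    """Strong-QTL cross with prescribed 8 het / 4 hom sires, 80 offspring each."""
    cfg = cf.lk_config(
        gmap, seed=21, n_f2=960, n_f1=24, n_f0_sires=6, n_f0_dams=6,
        qtl_var_share=0.4, sire_qtl_pattern=tuple(["het"] * 8 + ["hom"] * 4),
    )
    return cf.simulate(cfg, gmap), cfg


@pytest.fixture(scope="session")
def kinship_medium(cross_medium):
    from crossfsv import grammar

    cross, _ = cross_medium
    ids, A = grammar.kinship_from_pedigree(cross.pedigree)
    return np.asarray(ids), A
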