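import numpy as np
import pandas as pd
import pytest

import omicsforest as of


@pytest.fixture(scope="session")
def small_map() -> of.GeneticMap:
    return of.simulate_map(5, 8, 10.0)


@pytest.fixture(scope="session")
def small_geno(small_map) -> of.GenotypeMatrix:
    return of.simulate_backcross(small_map, 120, seed=11)


def make_planted_study(seed: int, n: int = 96, n_noise_gene: int = 60,
                       n_noise_lc: int = 30) -> of.SyntheticStudy:
    """Small study with trait QTLs on groups 2 and 4, cis transcripts
    tagging them, and a transcript -> metabolite chain."""
    gmap = of.simulate_map(5, 8, 10.0)
    geno = of.simulate_backcross(gmap, n, seed=seed)
    arch = of.Architecture(
        n_individuals=n,
        trait_qtls=[("M2_4", 1.2), ("M4_3", 1.0)],
        cis_features=[
            of.FeatureSpec("Gene_1", "gene", "M2_4", 2.0, 1.0),
            of.FeatureSpec("Gene_2", "gene", "M4_3", 2.0, 1.0),
        ],
        trans_features=[of.FeatureSpec("Gene_3", "gene", "M2_4", 1.5, 1.0)],
        pathway_chains=[of.PathwayChain("Gene_1", (("LC_1", "lc", 1.0, 1.0),))],
        n_noise_per_layer={"gene": n_noise_gene, "lc": n_noise_lc},
        trait_noise_sd=1.0,
        annotation_unknown_rate=0.0,
        seed=seed + 1000,
    )
    return of.simulate_study(gmap, geno, arch)


@pytest.fixture()
def planted_study() -> of.SyntheticStudy:
    return make_planted_study(seed=5)


def study_bundle(study: of.SyntheticStudy, with_genetics: bool = True) -> of.StudyBundle:
    return of.StudyBundle(
        layers=study.layers,
        traits=study.traits,
        genotypes=study.genotypes if with_genetics else None,
        gmap=study.gmap if with_genetics else None,
        annotation=study.annotation,
    )
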