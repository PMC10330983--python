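import numpy as np
import pandas as pd
import pytest

from sweepscan import simdata
from sweepscan.vario import VariantTable


def make_table(genotype_rows, positions=None, chrom="chr1", samples=None,
               populations=None, ref="A", alt="G", qd=20.0, fs=1.0, mq=50.0,
               gq=None):
    """Hand-build a VariantTable from per-site lists of (a, b) allele pairs."""
    g = np.asarray(genotype_rows, dtype=np.int8)
    n_sites, n_samples = g.shape[:2]
    if positions is None:
        positions = [100 * (i + 1) for i in range(n_sites)]
    if samples is None:
        samples = [f"s{j + 1}" for j in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": chrom, "pos": positions,
        "ref": [ref] * n_sites if isinstance(ref, str) else ref,
        "alt": [alt] * n_sites if isinstance(alt, str) else alt,
        "qd": qd, "fs": fs, "mq": mq})
    return VariantTable(sites=sites, genotypes=g, samples=samples,
                        populations=populations or {}, gq=gq)


@pytest.fixture(scope="session")
def sweep_cohort():
    """2 populations x 20 diploids, one 200-kb sweep (reduction 0.8) on a
    5-Mb chromosome with 5,000 sites."""
    cfg = simdata.SimConfig(
        seed=1, n_pops=2, samples_per_pop=20, chrom_lengths=(5_000_000,),
        n_sites=5_000, background_fst=0.05,
        sweep_specs=(simdata.SweepSpec("pop2", "chr1", 2_000_000, 2_200_000, 0.8),))
    table, truth = simdata.simulate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A small cohort written to disk in every standard format."""
    cfg = simdata.SimConfig(
        seed=11, n_pops=2, samples_per_pop=8, chrom_lengths=(400_000,),
        n_sites=600, background_fst=0.05,
        sweep_specs=(simdata.SweepSpec("pop2", "chr1", 150_000, 250_000, 0.8),),
        causal_spec=simdata.CausalSpec(0, 1, 1.0))
    table, truth = simdata.simulate_cohort(cfg)
    out = tmp_path_factory.mktemp("fixture")
    paths = simdata.write_fixture(table, truth, out, cfg)
    return cfg, table, truth, paths
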