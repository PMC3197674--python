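import numpy as np
import pytest

from ultraedit.align import Genome
from ultraedit.pipeline import run_pipeline
from ultraedit.prefilter import SeqRecord
from ultraedit.simulate import SimConfig, simulate_cohort
from ultraedit.transform import reverse_complement


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def toy_genome():
    rg = np.random.default_rng(7)
    seq = "".join(rg.choice(list("ACGT"), 4000))
    return Genome({"chr1": seq})


@pytest.fixture(scope="session")
def clean_cohort():
    """50 edited reads, per-adenosine rate 0.25, 300 bp repeats, 0.1% errors."""
    cfg = SimConfig(seed=1)
    sim, reads, truths = simulate_cohort(cfg, "clean", n_reads=50)
    return sim, reads, truths


@pytest.fixture(scope="session")
def clean_run(clean_cohort):
    sim, reads, truths = clean_cohort
    result = run_pipeline(reads, sim.genome, repeats=sim.repeats)
    return sim, reads, truths, result


@pytest.fixture(scope="session")
def artifact_cohort():
    cfg = SimConfig(seed=3)
    sim, reads, truths = simulate_cohort(cfg, "artifacts", n_reads=20)
    return sim, reads, truths


@pytest.fixture(scope="session")
def artifact_run(artifact_cohort):
    sim, reads, truths = artifact_cohort
    result = run_pipeline(reads, sim.genome, repeats=sim.repeats)
    return sim, reads, truths, result


@pytest.fixture(scope="session")
def rc_cohort_runs():
    """A cohort and the same cohort with every read reverse-complemented."""
    cfg = SimConfig(seed=5)
    sim, reads, truths = simulate_cohort(cfg, "clean", n_reads=30)
    fwd = run_pipeline(reads, sim.genome, repeats=sim.repeats)
    rc_reads = [SeqRecord(r.id, reverse_complement(r.seq)) for r in reads]
    rev = run_pipeline(rc_reads, sim.genome, repeats=sim.repeats)
    return sim, truths, fwd, rev
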