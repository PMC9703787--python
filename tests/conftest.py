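import numpy as np
import pytest

from mitoscaffold import (
    SimConfig,
    assign_copy_class,
    build_scaffolds,
    fragment_to_contigs,
    select_mito_contigs,
    simulate_long_reads,
    simulate_mitogenome,
)


def random_dna(n: int, seed: int = 0, gc: float = 0.5) -> str:
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def scaffold_run(seed: int, **cfg_kwargs):
    """Simulate -> fragment -> select -> classify -> scaffold, returning
    (truth, contigs, result)."""
    truth = simulate_mitogenome(SimConfig(seed=seed, **cfg_kwargs))
    contigs, _ = fragment_to_contigs(truth)
    select_mito_contigs(contigs)
    assign_copy_class(contigs)
    result = build_scaffolds(contigs, simulate_long_reads(truth))
    return truth, contigs, result


@pytest.fixture(scope="session")
def default_run():
    """One full scaffolding run on the default study conditions."""
    return scaffold_run(seed=7)
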