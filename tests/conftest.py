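import pytest
from hypothesis import HealthCheck, settings

from wildtcr.repertoire_io import AAKey, Repertoire
from wildtcr.simulate import ChainConfig, SimulationConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_repertoire(counts, mouse_id="m1", subset="CD4", chain="alpha"):
    """Repertoire with synthetic single-letter clonotype keys and the given
    counts (dict label -> count, or an iterable of counts)."""
    if not isinstance(counts, dict):
        counts = {f"K{i}": c for i, c in enumerate(counts)}
    clones = {AAKey(f"V{lbl}", f"CDR{lbl}", f"J{lbl}"): int(c)
              for lbl, c in counts.items()}
    return Repertoire(mouse_id=mouse_id, subset=subset, chain=chain,
                      clones=clones, level="amino_acid")


def small_sim_config(n_mice=8, seed=4, n_unique=400, **kwargs):
    """A fast, downsized simulation config for structural tests."""
    chains = {
        "alpha": ChainConfig(n_unique=n_unique, pool_size=max(60, n_unique // 2),
                             public_fraction=0.06,
                             v_catalog=("TRAV1", "TRAV2", "TRAV3"),
                             j_catalog=("TRAJ1", "TRAJ2")),
        "beta": ChainConfig(n_unique=n_unique, pool_size=max(60, n_unique // 2),
                            public_fraction=0.025,
                            v_catalog=("TRBV1", "TRBV2", "TRBV3"),
                            j_catalog=("TRBJ1", "TRBJ2")),
    }
    return SimulationConfig(n_mice=n_mice, seed=seed, chains=chains, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """One downsized cohort shared by structural tests (8 mice, 400
    clonotypes per repertoire)."""
    return simulate_cohort(small_sim_config())
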