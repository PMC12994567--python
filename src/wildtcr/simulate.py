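"""Synthetic TCR repertoire cohorts with the statistical structure the
analysis assumes.

The generator emulates four features of wild-mouse repertoire data:

* power-law-distributed clone sizes (discrete, exponent per chain),
* greater clonotype sharing for alpha than beta chains, via a larger public
  fraction drawn from a per-chain public pool,
* a public clonotype pool sampled with Zipf-decaying popularity, so a small
  head of pool clonotypes recurs in most mice (public clonotypes) while the
  rest are shared only sporadically,
* age- and sex-linked expansion of a small "chronic" subset of clones: their
  relative abundance is multiplied by exp(beta * age * sex_multiplier) and
  the repertoire re-normalised to its original sequencing depth, which
  lowers Shannon/Simpson diversity with age while leaving both the number of
  unique clonotypes and the molecule total per repertoire essentially
  constant — expansion changes composition, not sequencing depth.

Defaults are desk-scale study conditions: 60 mice aged 2-49 weeks from two
sites, 5000 unique clonotypes per repertoire, clone-size exponent 2.5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .powerlaw import sample_discrete_powerlaw
from .repertoire_io import (
    AAKey,
    MouseMetadata,
    Repertoire,
    write_clonotype_table,
    write_metadata,
)
from .seeds import derive_rng, derive_seed

__all__ = [
    "ChainConfig",
    "SimulationConfig",
    "PublicPool",
    "Cohort",
    "sample_clone_sizes",
    "make_clonotype_pool",
    "simulate_mouse",
    "simulate_cohort",
]

_AA_BYTES = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)


@dataclass
class ChainConfig:
    """Per-chain generator settings (alpha and beta differ in catalogs and
    in how much of each repertoire comes from the public pool)."""

    alpha_exponent: float = 2.5
    xmin: int = 1
    n_unique: int = 5000
    public_fraction: float = 0.06
    pool_size: int = 3000
    pool_zipf: float = 1.5
    v_catalog: Tuple[str, ...] = ()
    j_catalog: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.alpha_exponent <= 1.0:
            raise ValueError("alpha_exponent must be > 1")
        if not 0.0 <= self.public_fraction <= 1.0:
            raise ValueError("public_fraction must be in [0, 1]")
        if self.n_unique < 1:
            raise ValueError("n_unique must be >= 1")


def _default_chains() -> Dict[str, ChainConfig]:
    return {
        "alpha": ChainConfig(
            public_fraction=0.06,
            v_catalog=tuple(f"TRAV{i}" for i in range(1, 31)),
            j_catalog=tuple(f"TRAJ{i}" for i in range(1, 51)),
        ),
        "beta": ChainConfig(
            public_fraction=0.025,
            v_catalog=tuple(f"TRBV{i}" for i in range(1, 26)),
            j_catalog=tuple(f"TRBJ{i}" for i in range(1, 13)),
        ),
    }


@dataclass
class SimulationConfig:
    """Cohort-level generator settings.

    ``age_effect_beta`` is the per-week log-multiplier applied to the counts
    of the chronic clone subset; ``sex_effect`` scales it for one sex
    (``sex_effect_sex``), giving that sex a steeper diversity decline.
    """

    n_mice: int = 60
    seed: int = 0
    chains: Dict[str, ChainConfig] = field(default_factory=_default_chains)
    age_effect_beta: float = 0.05
    sex_effect: float = 1.5
    sex_effect_sex: str = "M"
    chronic_fraction: float = 0.01
    age_range: Tuple[float, float] = (2.0, 49.0)
    sites: Tuple[Tuple[str, float], ...] = (("Nottingham", 0.94), ("Wirral", 0.06))
    cdr3_length_range: Tuple[int, int] = (10, 16)

    def __post_init__(self) -> None:
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range min must be <= max")
        if self.cdr3_length_range[0] > self.cdr3_length_range[1]:
            raise ValueError("cdr3_length_range min must be <= max")
        if isinstance(self.chains, dict):
            self.chains = {
                k: (v if isinstance(v, ChainConfig) else ChainConfig(**v))
                for k, v in self.chains.items()
            }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("age_range", "cdr3_length_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "sites" in d and d["sites"] is not None:
            d["sites"] = tuple((s, float(w)) for s, w in d["sites"])
        if "chains" in d and d["chains"] is not None:
            chains = {}
            for name, cc in d["chains"].items():
                if isinstance(cc, ChainConfig):
                    chains[name] = cc
                else:
                    cc = dict(cc)
                    for key in ("v_catalog", "j_catalog"):
                        if key in cc:
                            cc[key] = tuple(cc[key])
                    chains[name] = ChainConfig(**cc)
            d["chains"] = chains
        return cls(**d)


@dataclass
class PublicPool:
    """Per-chain pool of amino-acid clonotypes shared across simulated mice.

    Pool members are sampled per mouse without replacement with probability
    proportional to rank^(-zipf), so low ranks form the public head."""

    chain: str
    keys: List[AAKey]
    zipf: float = 1.5

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("pool keys must be unique")
        self._key_set = frozenset(self.keys)

    @property
    def key_set(self) -> frozenset:
        return self._key_set


@dataclass
class Cohort:
    """An in-memory simulated cohort: metadata plus repertoires keyed by
    (mouse_id, receptor_type)."""

    metadata: List[MouseMetadata]
    repertoires: Dict[Tuple[str, str], Repertoire]
    config: SimulationConfig
    pools: Dict[str, PublicPool]

    def metadata_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"mouse_id": m.mouse_id, "sex": m.sex, "age": m.age,
                 "site": m.site, "cohort": m.cohort}
                for m in self.metadata
            ]
        )


def sample_clone_sizes(
    n: int, alpha: float, xmin: int = 1, seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Draw ``n`` clone sizes from the discrete power law P(k) ~ k^-alpha,
    k >= xmin.  Reproducible under ``seed``."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return sample_discrete_powerlaw(n, alpha, xmin, rng)


def _random_cdr3s(n: int, length_range: Tuple[int, int],
                  rng: np.random.Generator) -> List[str]:
    """Vectorised uniform CDR3 amino-acid strings."""
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    out = np.empty(n, dtype=object)
    for length in np.unique(lengths):
        idx = np.flatnonzero(lengths == length)
        codes = _AA_BYTES[rng.integers(0, 20, size=(idx.size, int(length)))]
        out[idx] = codes.view(f"S{int(length)}").ravel().astype(str)
    return out.tolist()


def _random_aakeys(
    n: int,
    v_catalog: Sequence[str],
    j_catalog: Sequence[str],
    length_range: Tuple[int, int],
    rng: np.random.Generator,
    exclude: Optional[set] = None,
) -> List[AAKey]:
    """Generate ``n`` distinct random clonotype keys, rejecting collisions
    with each other and with ``exclude``."""
    if not v_catalog or not j_catalog:
        raise ValueError("V/J catalogs must be non-empty")
    exclude = exclude if exclude is not None else frozenset()
    # plain tuples: hash/equality-compatible with AAKey, much cheaper to build
    keys: List[AAKey] = []
    seen: set = set()
    need = n
    v_arr, j_arr = list(v_catalog), list(j_catalog)
    while need > 0:
        cdr3s = _random_cdr3s(need, length_range, rng)
        vs = rng.integers(0, len(v_arr), size=need)
        js = rng.integers(0, len(j_arr), size=need)
        for key in zip((v_arr[i] for i in vs), cdr3s, (j_arr[i] for i in js)):
            if key in seen or key in exclude:
                continue
            seen.add(key)
            keys.append(key)
        need = n - len(keys)
    return keys


def make_clonotype_pool(
    n: int, config: SimulationConfig, chain: str, seed: int
) -> PublicPool:
    """Generate the per-chain public pool: ``n`` unique clonotype keys with
    uniform CDR3 composition over the configured length range."""
    if n < 1:
        raise ValueError("pool size must be >= 1")
    cc = config.chains[chain]
    rng = derive_rng(seed, "pool", chain)
    keys = _random_aakeys(n, cc.v_catalog, cc.j_catalog,
                          config.cdr3_length_range, rng)
    return PublicPool(chain=chain, keys=keys, zipf=cc.pool_zipf)


def _weighted_pool_pick(pool: PublicPool, k: int,
                        rng: np.random.Generator) -> List[AAKey]:
    """Weighted sampling without replacement (Efraimidis-Spirakis keys)."""
    m = len(pool.keys)
    if k > m:
        raise ValueError(f"cannot pick {k} keys from pool of {m}")
    if k == 0:
        return []
    ranks = np.arange(1, m + 1, dtype=np.float64)
    w = ranks ** (-pool.zipf)
    g = np.log(rng.random(m)) / w
    top = np.argpartition(g, m - k)[m - k:]
    return [pool.keys[i] for i in top]


def simulate_mouse(
    meta: MouseMetadata,
    config: SimulationConfig,
    pools: Dict[str, PublicPool],
    seed: int,
) -> Dict[str, Repertoire]:
    """Simulate the four repertoires (CD4/CD8 x alpha/beta) of one mouse.

    Each repertoire holds exactly ``n_unique`` clonotypes: a public slice
    drawn from the chain's pool and a freshly generated private remainder.
    Base counts are power-law draws; the chronic subset (a random
    ``chronic_fraction`` of clonotypes) has its relative abundance inflated
    by exp(age_effect_beta * age * sex_multiplier) and the counts are
    re-normalised to the base molecule total (every count floored at 1), so
    richness and depth are untouched while evenness — hence diversity —
    declines with age.
    """
    lo, hi = config.age_range
    if not lo <= meta.age <= hi:
        raise ValueError(f"age {meta.age} outside configured range {config.age_range}")
    sex_mult = config.sex_effect if meta.sex == config.sex_effect_sex else 1.0
    expansion = float(np.exp(config.age_effect_beta * meta.age * sex_mult))
    out: Dict[str, Repertoire] = {}
    for subset in ("CD4", "CD8"):
        for chain in ("alpha", "beta"):
            cc = config.chains[chain]
            rng = derive_rng(seed, meta.mouse_id, subset, chain)
            n_pub = int(round(cc.public_fraction * cc.n_unique))
            pub = _weighted_pool_pick(pools[chain], n_pub, rng)
            priv = _random_aakeys(
                cc.n_unique - n_pub, cc.v_catalog, cc.j_catalog,
                config.cdr3_length_range, rng,
                exclude=pools[chain].key_set,
            )
            keys = pub + priv
            base = sample_discrete_powerlaw(
                cc.n_unique, cc.alpha_exponent, cc.xmin, rng
            )
            n_chronic = max(1, int(round(config.chronic_fraction * cc.n_unique)))
            chronic = rng.choice(cc.n_unique, size=n_chronic, replace=False)
            counts = base.copy()
            increment = (np.round(base[chronic] * expansion)
                         .astype(np.int64) - base[chronic])
            # the chronic excess is paid for by the non-chronic clones' spare
            # molecules (those above each clone's first), so total depth is
            # exactly preserved and no clonotype is lost; expansion saturates
            # when the spare pool cannot cover it
            spare = np.maximum(base - 1, 0)
            spare[chronic] = 0
            spare_total = int(spare.sum())
            if increment.sum() > spare_total:
                increment = (increment * (spare_total / increment.sum())
                             ).astype(np.int64)
            counts[chronic] = base[chronic] + increment
            excess = int(increment.sum())
            if excess > 0:
                removed = rng.multivariate_hypergeometric(spare, excess)
                counts = counts - removed
            clones = dict(zip(keys, counts.tolist()))
            out[f"{subset}_{chain}"] = Repertoire(
                mouse_id=meta.mouse_id, subset=subset, chain=chain,
                clones=clones, level="amino_acid",
            )
    return out


def _simulate_metadata(config: SimulationConfig) -> List[MouseMetadata]:
    rng = derive_rng(config.seed, "metadata")
    site_labels = [s for s, _ in config.sites]
    site_w = np.asarray([w for _, w in config.sites], dtype=np.float64)
    site_w = site_w / site_w.sum()
    width = max(3, len(str(config.n_mice)))
    out = []
    for i in range(config.n_mice):
        sex = "M" if rng.random() < 0.5 else "F"
        age = float(np.round(rng.uniform(*config.age_range), 1))
        site = site_labels[int(rng.choice(len(site_labels), p=site_w))]
        out.append(MouseMetadata(mouse_id=f"M{i + 1:0{width}d}", sex=sex,
                                 age=age, site=site, cohort="wild"))
    return out


def simulate_cohort(
    config: SimulationConfig, out_dir: Optional[Path] = None
) -> Cohort:
    """Simulate a full cohort; optionally write it to disk.

    When ``out_dir`` is given, one AIRR TSV per (mouse, subset, chain) plus
    ``metadata.tsv`` and a ``simulation_config.json`` echo are written; the
    output is byte-identical across runs with the same config.
    """
    pools = {
        chain: make_clonotype_pool(cc.pool_size, config, chain, config.seed)
        for chain, cc in config.chains.items()
    }
    metadata = _simulate_metadata(config)
    repertoires: Dict[Tuple[str, str], Repertoire] = {}
    for meta in metadata:
        mouse_seed = derive_seed(config.seed, "mouse", meta.mouse_id)
        for rt, rep in simulate_mouse(meta, config, pools, mouse_seed).items():
            repertoires[(meta.mouse_id, rt)] = rep
    cohort = Cohort(metadata=metadata, repertoires=repertoires,
                    config=config, pools=pools)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_metadata(metadata, out_dir / "metadata.tsv")
        with (out_dir / "simulation_config.json").open("w") as handle:
            json.dump(config.to_dict(), handle, indent=2, sort_keys=True)
            handle.write("\n")
        for (mouse_id, rt), rep in sorted(repertoires.items()):
            write_clonotype_table(rep, out_dir / f"{mouse_id}_{rt}.tsv",
                                  dialect="airr")
    return cohort
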