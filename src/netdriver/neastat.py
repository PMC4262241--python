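"""Randomization-calibrated network enrichment statistics.

The enrichment of links between a query (one gene, or a set tested for its
own coherence) and a target gene set is scored as

    z = (n_obs - mean_null) / sd_null

where the null moments come from link counts recomputed on degree-preserving
rewired replicas of the network. Because node degrees in functional-coupling
networks follow a heavy-tailed distribution, this degree-conditioned null is
essential: a hub query accumulates links to any set by chance alone.

Also provided: the normal-tail z→p conversion, Fisher's combined probability
(chi-square of -2 Σ ln p on 2k degrees of freedom) and the 2x2 Fisher exact
test used for mutation co-occurrence screening.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .graphnet import (
    GeneNetwork,
    RewireConfig,
    direct_links,
    mapped_members,
    rewire,
    shared_neighbor_links,
    within_set_links,
)

logger = logging.getLogger("netdriver")

__all__ = [
    "N_RANDOMIZATIONS",
    "Z_CAP",
    "P_FLOOR",
    "NullEnsemble",
    "NeaResult",
    "CombinedPValue",
    "null_moments",
    "nea_gene_vs_set",
    "nea_set_coherence",
    "z_to_p",
    "fisher_combine",
    "fisher_exact_2x2",
]

#: Default number of degree-preserving randomizations behind the null moments.
N_RANDOMIZATIONS = 25

#: Cap applied to z when the null sd is zero but the observed count differs
#: from the (degenerate) null mean; keeps p-values representable.
Z_CAP = 40.0

#: Floor for component p-values entering -2 ln p.
P_FLOOR = 1e-300


@dataclass
class NeaResult:
    """One gene-vs-set (or within-set) enrichment test."""

    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    mode: str
    query: str
    target: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p out of range: {self.p}")
        if self.null_sd > 0:
            expect = (self.observed - self.null_mean) / self.null_sd
            if not math.isclose(self.z, expect, rel_tol=1e-12, abs_tol=1e-12):
                raise ValueError("stored z inconsistent with moments")


@dataclass
class CombinedPValue:
    """Fisher's combined probability over k component tests."""

    chi2: float
    df: int
    p: float
    components: list[float] = field(default_factory=list)


class NullEnsemble:
    """A fixed set of rewired replicas of one network.

    One ensemble (default 25 replicas) serves every enrichment test in a run:
    the replicas are generated once, then any count function is re-evaluated
    on each of them. Replica seeds are derived deterministically from the
    master seed and the replica index.
    """

    def __init__(
        self,
        network: GeneNetwork,
        n_rand: int = N_RANDOMIZATIONS,
        seed: int = 0,
        rewire_cfg: RewireConfig | None = None,
    ):
        if n_rand < 2:
            raise ValueError("need at least 2 randomizations (sd undefined below)")
        self.network = network
        self.n_rand = n_rand
        self.seed = seed
        base = rewire_cfg or RewireConfig(seed=seed)
        self.replicas: list[GeneNetwork] = []
        for k in range(n_rand):
            rep_seed = int(
                np.random.SeedSequence(entropy=[seed, k]).generate_state(1)[0]
                % (2**31)
            )
            cfg = RewireConfig(
                swap_factor=base.swap_factor,
                seed=rep_seed,
                max_attempt_factor=base.max_attempt_factor,
            )
            self.replicas.append(rewire(network, cfg))

    def counts(self, count_fn: Callable[[GeneNetwork], int]) -> np.ndarray:
        return np.array([count_fn(rep) for rep in self.replicas], dtype=float)

    @classmethod
    def for_network(
        cls,
        network: GeneNetwork,
        n_rand: int = N_RANDOMIZATIONS,
        seed: int = 0,
        rewire_cfg: RewireConfig | None = None,
    ) -> "NullEnsemble":
        """Return a cached ensemble for (network, seed, n_rand, swap params)."""
        base = rewire_cfg or RewireConfig(seed=seed)
        key = (n_rand, seed, base.swap_factor, base.max_attempt_factor)
        cache = network._ensemble_cache
        if key not in cache:
            cache[key] = cls(network, n_rand=n_rand, seed=seed, rewire_cfg=rewire_cfg)
        return cache[key]


def _count_fn(query, target, mode: str) -> Callable[[GeneNetwork], int]:
    if isinstance(query, str):
        if mode == "direct":
            return lambda net: direct_links(net, query, target)
        if mode == "shared":
            return lambda net: shared_neighbor_links(net, query, target)
    else:  # within-set coherence
        if mode in ("direct", "shared"):
            return lambda net: within_set_links(net, query, mode)
    raise ValueError(f"unknown mode {mode!r}")


def null_moments(
    net: GeneNetwork,
    query,
    target: Iterable[str] | None = None,
    mode: str = "direct",
    n_rand: int = N_RANDOMIZATIONS,
    seed: int = 0,
    rewire_cfg: RewireConfig | None = None,
    ensemble: NullEnsemble | None = None,
) -> tuple[float, float, NullEnsemble]:
    """Null mean and sd of the link count from rewired replicas.

    The sd is the sample standard deviation (ddof=1) over the replicas.
    """
    if ensemble is None:
        ensemble = NullEnsemble.for_network(net, n_rand=n_rand, seed=seed, rewire_cfg=rewire_cfg)
    counts = ensemble.counts(_count_fn(query, target, mode))
    return float(counts.mean()), float(counts.std(ddof=1)), ensemble


def _z_from_moments(observed: float, mean: float, sd: float) -> float:
    if sd > 0:
        return (observed - mean) / sd
    if observed == mean:
        return 0.0
    return math.copysign(Z_CAP, observed - mean)


def z_to_p(z: float, convention: str = "one_sided") -> float:
    """Normal-tail probability of a z-score.

    ``one_sided`` is the upper tail (enrichment is directional);
    ``two_sided`` doubles the tail of |z|, capped at 1.
    """
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    if convention == "one_sided":
        return float(stats.norm.sf(z))
    if convention == "two_sided":
        return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    raise ValueError(f"unknown convention {convention!r}")


def nea_gene_vs_set(
    net: GeneNetwork,
    i: str,
    G: Iterable[str],
    mode: str = "direct",
    n_rand: int = N_RANDOMIZATIONS,
    seed: int = 0,
    rewire_cfg: RewireConfig | None = None,
    ensemble: NullEnsemble | None = None,
    convention: str = "one_sided",
    target_name: str = "",
) -> NeaResult:
    """Enrichment of links between a single gene and a gene set.

    The query gene is always excluded from the target set. The same count is
    recomputed on every rewired replica to obtain the null moments.
    """
    if i not in net:
        raise KeyError(f"query gene {i!r} not in network")
    members, missing = mapped_members(net, G)
    members.discard(i)
    if not members:
        raise ValueError(f"no mapped target genes for query {i!r}")
    if missing:
        logger.debug("query %s: %d target gene(s) unmapped", i, len(missing))
    observed = direct_links(net, i, members) if mode == "direct" else shared_neighbor_links(net, i, members)
    mean, sd, _ = null_moments(
        net, i, members, mode=mode, n_rand=n_rand, seed=seed,
        rewire_cfg=rewire_cfg, ensemble=ensemble,
    )
    z = _z_from_moments(observed, mean, sd)
    return NeaResult(
        observed=observed, null_mean=mean, null_sd=sd, z=z,
        p=z_to_p(z, convention), mode=mode, query=i, target=target_name,
    )


def nea_set_coherence(
    net: GeneNetwork,
    G: Iterable[str],
    mode: str = "direct",
    n_rand: int = N_RANDOMIZATIONS,
    seed: int = 0,
    rewire_cfg: RewireConfig | None = None,
    ensemble: NullEnsemble | None = None,
    convention: str = "one_sided",
    set_name: str = "",
) -> NeaResult:
    """Internal coherence of a gene set: within-set links against the
    degree-preserving null."""
    members, _ = mapped_members(net, G)
    if len(members) < 2:
        raise ValueError("set coherence needs >=2 mapped members")
    members = frozenset(members)
    observed = within_set_links(net, members, mode)
    mean, sd, _ = null_moments(
        net, members, None, mode=mode, n_rand=n_rand, seed=seed,
        rewire_cfg=rewire_cfg, ensemble=ensemble,
    )
    z = _z_from_moments(observed, mean, sd)
    return NeaResult(
        observed=observed, null_mean=mean, null_sd=sd, z=z,
        p=z_to_p(z, convention), mode=mode, query=set_name or "<set>",
        target=set_name or "<set>",
    )


def fisher_combine(ps: Sequence[float], p_floor: float = P_FLOOR) -> CombinedPValue:
    """Fisher's method: chi2 = -2 Σ ln p on 2k degrees of freedom.

    Component p-values of exactly zero are floored at ``p_floor`` (with a
    warning) so the log is defined.
    """
    ps = list(ps)
    if not ps:
        raise ValueError("cannot combine an empty p-value list")
    comps = []
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value out of range: {p}")
        if p < p_floor:
            logger.warning("component p=%g floored at %g", p, p_floor)
            p = p_floor
        comps.append(float(p))
    chi2 = -2.0 * sum(math.log(p) for p in comps)
    df = 2 * len(comps)
    return CombinedPValue(chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)), components=comps)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sided: str = "one") -> float:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    One-sided: probability, under fixed margins, of a table at least as
    enriched in cell ``a`` (hypergeometric upper tail). Two-sided: sum of all
    tables whose point probability does not exceed the observed one.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d < 1:
        raise ValueError("table total must be >= 1")
    if sided == "one":
        # P(X >= a) with X ~ Hypergeom(N, K=a+b, n=a+c)
        return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))
    if sided == "two":
        return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    raise ValueError(f"unknown sidedness {sided!r}")
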