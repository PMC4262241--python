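"""ROC-based benchmarking of candidate global networks.

A network is judged by how well enrichment z-scores recover known pathway
membership: each member gene of each functional gene set is tested against
the rest of its set (a true test), and paired with a test of a randomly
picked degree-matched non-member against the same rest-of-set (a null test).
Sweeping a decreasing z threshold over the pooled scores gives counts of
true positives (Y) versus false positives (X); curves terminate at the
lowest formally significant z (default 1.97). Because of the termination the
area under the curve is not comparable across networks; the headline metric
is the Y/X ratio ("odds ratio") at the point where the empirical false
discovery rate X/(X+Y) first reaches a set level (default 0.1), plus the
total count of recapitulated true members.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .driverscan import PathwayCollection
from .graphnet import GeneNetwork, mapped_members
from .neastat import N_RANDOMIZATIONS, NullEnsemble, nea_gene_vs_set

logger = logging.getLogger("netdriver")

__all__ = [
    "Z_MIN",
    "BenchmarkConfig",
    "RocCurve",
    "OrResult",
    "degree_matched_substitute",
    "membership_tests",
    "build_roc",
    "or_at_fdr",
    "benchmark_networks",
]

#: ROC termination threshold: lowest formally significant z.
Z_MIN = 1.97


@dataclass(frozen=True)
class BenchmarkConfig:
    """Benchmark settings.

    ``fdr_cross`` is the empirical FDR level at which the Y/X ratio is read
    off; ``degree_tolerance`` is the relative half-width of the degree window
    used when picking substitutes (widened geometrically until a candidate
    exists).
    """

    fdr_cross: float = 0.1
    degree_tolerance: float = 0.1
    z_min: float = Z_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_cross < 1:
            raise ValueError("fdr_cross must be in (0, 1)")


@dataclass
class RocCurve:
    """Membership-recovery ROC from paired true/null z-scores.

    ``points`` are (false-positive count X, true-positive count Y) at
    decreasing z thresholds, both non-decreasing along the curve; thresholds
    below ``z_min`` are not swept.
    """

    points: list[tuple[int, int]]
    thresholds: list[float]
    z_min: float
    n_true_tests: int
    n_null_tests: int


@dataclass
class OrResult:
    """Y/X ratio at the FDR cross point.

    ``ratio`` is math.inf when X = 0 at the reporting point (flagged
    ``undefined``) and nan when the curve has no points at all.
    ``lower_bound`` marks curves that never reach the FDR level, where the
    terminal point is reported instead.
    """

    ratio: float
    x: int
    y: int
    threshold: float
    lower_bound: bool = False
    undefined: bool = False


def degree_matched_substitute(
    net: GeneNetwork,
    member: str,
    exclude: set[str],
    tolerance: float = 0.1,
    rng: np.random.Generator | None = None,
    widen: bool = True,
) -> str:
    """Pick a random non-excluded gene whose degree matches ``member``'s.

    The candidate window is ``|k - k_member| <= tolerance * k_member``
    (at least ±0 in absolute terms); if empty it widens geometrically
    (doubling) until a candidate exists, unless ``widen`` is False.
    """
    rng = rng or np.random.default_rng()
    k0 = net.degree(member)
    degs = net.degrees()
    scale = max(k0, 1)  # absolute slack for degree-0 members
    tol = tolerance
    while True:
        lo, hi = k0 - tol * scale, k0 + tol * scale
        candidates = [g for g, k in degs.items() if lo <= k <= hi and g not in exclude]
        if candidates:
            candidates.sort()
            return candidates[int(rng.integers(0, len(candidates)))]
        if not widen or (lo <= 0 and hi >= max(degs.values(), default=0)):
            raise ValueError(
                f"no degree-matched substitute for {member!r} (degree {k0})"
            )
        tol = max(2 * tol, 0.01)


def membership_tests(
    net: GeneNetwork,
    collection: PathwayCollection,
    ensemble: NullEnsemble | None = None,
    cfg: BenchmarkConfig | None = None,
    n_rand: int = N_RANDOMIZATIONS,
    mode: str = "direct",
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out membership recovery over every set of the collection.

    For each set G and each mapped member i: a true test z(i vs G \\ {i}) and
    a paired null test z(i' vs G \\ {i}) where i' is a degree-matched
    substitute that is not a member of G. Returns equal-length arrays of true
    and null z-scores.
    """
    cfg = cfg or BenchmarkConfig()
    if ensemble is None:
        ensemble = NullEnsemble.for_network(net, n_rand=n_rand, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    true_z: list[float] = []
    null_z: list[float] = []
    for name in sorted(collection.sets):
        members, _ = mapped_members(net, collection.sets[name])
        if len(members) < 2:
            logger.warning("set %s has <2 mapped members; skipped", name)
            continue
        for i in sorted(members):
            rest = members - {i}
            res_true = nea_gene_vs_set(net, i, rest, mode=mode, ensemble=ensemble, target_name=name)
            sub = degree_matched_substitute(
                net, i, exclude=set(members), tolerance=cfg.degree_tolerance, rng=rng
            )
            res_null = nea_gene_vs_set(net, sub, rest, mode=mode, ensemble=ensemble, target_name=name)
            true_z.append(res_true.z)
            null_z.append(res_null.z)
    return np.asarray(true_z), np.asarray(null_z)


def build_roc(true_z, null_z, z_min: float = Z_MIN) -> RocCurve:
    """Sweep decreasing z thresholds and accumulate (X, Y) counts.

    Thresholds are the union of observed z values at or above ``z_min``, in
    decreasing order; ties are processed as one step. Y counts true scores at
    or above the threshold, X counts null scores.
    """
    true_z = np.asarray(true_z, dtype=float)
    null_z = np.asarray(null_z, dtype=float)
    if true_z.size == 0 or null_z.size == 0:
        raise ValueError("need non-empty true and null score lists")
    if true_z.size != null_z.size:
        raise ValueError("paired design requires equal-length score lists")
    thresholds = sorted(
        {float(z) for z in np.concatenate([true_z, null_z]) if z >= z_min},
        reverse=True,
    )
    points = []
    for t in thresholds:
        y = int((true_z >= t).sum())
        x = int((null_z >= t).sum())
        points.append((x, y))
    return RocCurve(
        points=points, thresholds=thresholds, z_min=z_min,
        n_true_tests=int(true_z.size), n_null_tests=int(null_z.size),
    )


def or_at_fdr(roc: RocCurve, fdr: float = 0.1) -> OrResult:
    """Y/X ratio at the first point (strictest threshold onward) where the
    empirical FDR X/(X+Y) reaches ``fdr``.

    If the curve never reaches the level, the terminal point's ratio is
    returned flagged as a lower bound; X = 0 gives an infinite, flagged
    ratio. The 1:1 paired design makes X/(X+Y) a conservative FDR estimate.
    """
    if not roc.points:
        return OrResult(ratio=float("nan"), x=0, y=0, threshold=float("nan"),
                        lower_bound=True, undefined=True)
    chosen = None
    for (x, y), t in zip(roc.points, roc.thresholds):
        if x + y and x / (x + y) >= fdr:
            chosen = (x, y, t, False)
            break
    if chosen is None:
        x, y = roc.points[-1]
        chosen = (x, y, roc.thresholds[-1], True)
    x, y, t, lower = chosen
    if x == 0:
        return OrResult(ratio=math.inf, x=x, y=y, threshold=t,
                        lower_bound=lower, undefined=True)
    return OrResult(ratio=y / x, x=x, y=y, threshold=t, lower_bound=lower)


def _ordering_key(res: OrResult) -> tuple:
    """Total order for comparing networks by their FDR-cross performance.

    Primary key: the Y/X ratio (curves with no point at all rank lowest;
    infinite ratios rank above any finite one). Ties — in particular two
    perfect, X = 0 curves — break on the true-positive count Y.
    """
    if math.isnan(res.ratio):
        return (-1.0, res.y)
    return (res.ratio, res.y)


def dominates(a: OrResult, b: OrResult) -> bool:
    """True when network result ``a`` strictly outperforms ``b``."""
    return _ordering_key(a) > _ordering_key(b)


def benchmark_networks(
    networks: dict[str, GeneNetwork],
    collection: PathwayCollection,
    cfg: BenchmarkConfig | None = None,
    n_rand: int = N_RANDOMIZATIONS,
    mode: str = "direct",
) -> tuple[pd.DataFrame, dict[str, RocCurve]]:
    """Benchmark several candidate networks on one pathway collection.

    Returns a summary table (one row per network: OR at the FDR cross, the
    cross coordinates, total recapitulated true members at z_min) and the
    full ROC curves.
    """
    cfg = cfg or BenchmarkConfig()
    rows = []
    curves: dict[str, RocCurve] = {}
    for name, net in networks.items():
        ensemble = NullEnsemble.for_network(net, n_rand=n_rand, seed=cfg.seed)
        tz, nz = membership_tests(net, collection, ensemble=ensemble, cfg=cfg, mode=mode)
        roc = build_roc(tz, nz, z_min=cfg.z_min)
        res = or_at_fdr(roc, fdr=cfg.fdr_cross)
        curves[name] = roc
        rows.append(
            {
                "network": name,
                "n_tests": roc.n_true_tests,
                "or_at_fdr": res.ratio,
                "or_x": res.x,
                "or_y": res.y,
                "or_lower_bound": res.lower_bound,
                "or_undefined": res.undefined,
                "total_true_recapitulated": int((tz >= cfg.z_min).sum()),
            }
        )
    return pd.DataFrame(rows), curves
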