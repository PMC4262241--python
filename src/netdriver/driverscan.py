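"""End-to-end driver-prioritization pipeline.

For each somatic alteration in a cohort, up to three network enrichment tests
are run against the global functional-coupling network:

* 1point-vs-MGS — is this point mutation connected to the other mutated
  genes of the same genome (its mutated gene set, MGS)?
* 1CNA-vs-MGS — is this copy-number-altered gene connected to the MGS of each
  genome that carries the alteration (per-genome p-values chi-square
  combined)?
* 1-vs-CPW — is the gene connected to known cancer pathways (the CAN
  category of the functional gene set collection)? Summed per-pathway
  z-scores are regularized by a fixed normalization factor.

Copy-number candidates are additionally screened for co-occurrence with point
mutations by Fisher's exact test. Available p-values per event are combined
by Fisher's method, Benjamini–Hochberg adjusted within each event class, and
events with adjusted p below the confidence threshold are called drivers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .graphnet import GeneNetwork, RewireConfig, mapped_members
from .neastat import (
    N_RANDOMIZATIONS,
    CombinedPValue,
    NeaResult,
    NullEnsemble,
    fisher_combine,
    fisher_exact_2x2,
    nea_gene_vs_set,
    nea_set_coherence,
    z_to_p,
)

logger = logging.getLogger("netdriver")

__all__ = [
    "MutationRecord",
    "Mgs",
    "CnaCall",
    "PathwayCollection",
    "CpwConfig",
    "CoocResult",
    "CombinedScore",
    "read_maf",
    "build_mgs",
    "read_cna_matrix",
    "call_cna",
    "read_gmt",
    "read_category_manifest",
    "test_point_vs_mgs",
    "test_cna_vs_mgs",
    "test_vs_cpw",
    "cooccurrence_scan",
    "combine_point",
    "combine_cna",
    "rank_and_adjust",
    "run_pipeline",
]

#: Gene-level |log2 copy-number| call threshold (strict inequality).
CNA_TAU = 0.35
#: Minimum number of genomes a gene must be called in to enter CNA analysis.
CNA_MIN_GENOMES = 3
#: Minimum mapped MGS size for the per-genome NEA tests.
MIN_MGS_SIZE = 3
#: Raw-p gate of the co-occurrence screen.
COOC_ALPHA = 0.01
#: Adjusted combined-p confidence threshold for a driver call (strict <).
DRIVER_THRESHOLD = 0.01


class MutationRecord(NamedTuple):
    sample: str
    gene: str
    variant_classification: str = ""


@dataclass(frozen=True)
class Mgs:
    """The mutated gene set of one tumor genome (duplicates collapsed)."""

    sample: str
    genes: frozenset[str]


@dataclass(frozen=True)
class CnaCall:
    gene: str
    sample: str
    log2: float
    direction: str  # "gain" | "loss"


@dataclass(frozen=True)
class CpwConfig:
    """1-vs-CPW settings.

    ``normalization_factor`` regularizes the sum of correlated per-pathway
    z-scores (default 10.16, the linear-fit coefficient of the super-pathway
    against the summed cancer pathways); ``z_cutoff`` (default 2.97) is the
    normalized-z significance cutoff corresponding to FDR 0.1.
    """

    normalization_factor: float = 10.16
    z_cutoff: float = 2.97
    mode: str = "sum_all_CAN"  # or "superpathway_only"
    floor_negative: bool = False

    def __post_init__(self) -> None:
        if self.normalization_factor <= 0:
            raise ValueError("normalization_factor must be positive")

    def normalize(self, z_sum: float) -> float:
        return z_sum / self.normalization_factor


@dataclass
class PathwayCollection:
    """Named functional gene sets with category tags.

    Categories follow the cohort analysis convention: ``CAN`` marks
    cancer-related pathways (the CPW collection); other tags (``SIG``,
    ``OTH``, custom) are carried through untouched. One CAN set may be
    designated the super-pathway (union-style umbrella set).
    """

    sets: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)
    superpathway: str | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        if self.superpathway is not None and self.superpathway not in self.sets:
            raise ValueError(f"super-pathway {self.superpathway!r} not in collection")

    def can_sets(self) -> dict[str, frozenset[str]]:
        return {
            n: g for n, g in self.sets.items() if self.categories.get(n) == "CAN"
        }


@dataclass
class CoocResult:
    """Co-occurrence screen outcome for one candidate gene."""

    gene: str
    n_partners_tested: int
    min_p: float
    best_partner: str | None
    p_co: float  # Bonferroni-corrected minimum
    passes: bool


@dataclass
class CombinedScore:
    """Hierarchically combined evidence for one alteration event."""

    event_id: str
    gene: str
    sample: str | None
    p_mgs: float | None
    p_cpw: float | None
    p_co: float | None
    chi2: float
    df: int
    combined_p: float
    adjusted_p: float = float("nan")
    driver_call: bool = False


# -- cohort input ----------------------------------------------------------


def read_maf(path) -> list[MutationRecord]:
    """Read somatic point mutations from a MAF-style TSV.

    Requires at least Hugo_Symbol and Tumor_Sample_Barcode columns; the
    Variant_Classification label is retained but never filtered on — every
    listed mutation enters the analysis.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("Hugo_Symbol", "Tumor_Sample_Barcode"):
        if col not in df.columns:
            raise ValueError(f"MAF is missing required column {col!r}")
    vc = df["Variant_Classification"] if "Variant_Classification" in df.columns else ""
    records = []
    for idx, row in df.iterrows():
        gene = str(row["Hugo_Symbol"]).strip().upper()
        sample = str(row["Tumor_Sample_Barcode"]).strip()
        if not gene or not sample or gene == "NAN":
            raise ValueError(f"empty gene or sample in MAF row {idx}")
        cls = str(vc.iloc[idx]) if isinstance(vc, pd.Series) else ""
        records.append(MutationRecord(sample=sample, gene=gene, variant_classification=cls))
    if not records:
        raise ValueError("MAF contains no mutation records")
    return records


def build_mgs(records: Iterable[MutationRecord]) -> dict[str, Mgs]:
    """Collapse records into one mutated gene set per sample.

    Multiple mutations of the same gene in one sample count once.
    """
    per_sample: dict[str, set[str]] = {}
    n_records = 0
    for rec in records:
        per_sample.setdefault(rec.sample, set()).add(rec.gene)
        n_records += 1
    mgs = {s: Mgs(sample=s, genes=frozenset(g)) for s, g in per_sample.items()}
    n_collapsed = n_records - sum(len(m.genes) for m in mgs.values())
    if n_collapsed:
        logger.info("collapsed %d duplicate gene-sample mutation record(s)", n_collapsed)
    return mgs


def read_cna_matrix(path) -> pd.DataFrame:
    """Read a gene x sample matrix of gene-level log2 copy-number values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.upper()
    bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric copy-number value at gene {row!r}, sample {col!r}")
    return df.astype(float)


def call_cna(
    profile: pd.DataFrame,
    tau: float = CNA_TAU,
    min_genomes: int = CNA_MIN_GENOMES,
) -> tuple[list[CnaCall], list[str]]:
    """Threshold the log2 matrix into per-gene-per-sample CNA calls.

    A call requires |log2| strictly above ``tau``; a gene is eligible for
    driver analysis when called in at least ``min_genomes`` genomes.
    """
    calls: list[CnaCall] = []
    eligible: list[str] = []
    values = profile.to_numpy()
    hit = np.abs(values) > tau
    for r, gene in enumerate(profile.index):
        cols = np.nonzero(hit[r])[0]
        for c in cols:
            calls.append(
                CnaCall(
                    gene=gene,
                    sample=str(profile.columns[c]),
                    log2=float(values[r, c]),
                    direction="gain" if values[r, c] > 0 else "loss",
                )
            )
        if len(cols) >= min_genomes:
            eligible.append(gene)
    return calls, eligible


# -- pathway input ---------------------------------------------------------


def read_gmt(path) -> dict[str, frozenset[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: need name, desc, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r} (line {lineno})")
            genes = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"gene set {name!r} is empty (line {lineno})")
            sets[name] = genes
    if not sets:
        raise ValueError("GMT file contains no gene sets")
    return sets


def read_category_manifest(path) -> tuple[dict[str, str], str | None]:
    """Read the set -> category map (YAML mapping or 2-column TSV).

    YAML layout: ``categories: {SET: CAN, ...}`` plus optional
    ``superpathway: SET``. TSV layout: ``set<TAB>category`` with an optional
    third field ``superpathway`` marking the umbrella set.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
        return dict(doc.get("categories", {})), doc.get("superpathway")
    categories: dict[str, str] = {}
    superpathway = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed manifest line: {line!r}")
        categories[fields[0]] = fields[1]
        if len(fields) > 2 and fields[2] == "superpathway":
            superpathway = fields[0]
    return categories, superpathway


def load_pathways(gmt_path, manifest_path=None) -> PathwayCollection:
    sets = read_gmt(gmt_path)
    if manifest_path is None:
        return PathwayCollection(sets=sets, categories={n: "CAN" for n in sets})
    categories, superpathway = read_category_manifest(manifest_path)
    return PathwayCollection(sets=sets, categories=categories, superpathway=superpathway)


# -- per-event tests -------------------------------------------------------


def test_point_vs_mgs(
    net: GeneNetwork,
    mgs: Mgs,
    gene: str,
    ensemble: NullEnsemble,
    mode: str = "direct",
    min_mgs: int = MIN_MGS_SIZE,
) -> NeaResult | None:
    """1point-vs-MGS: one point mutation against the rest of its genome's MGS.

    Returns None (test skipped, excluded from combination) when, after
    removing the query and unmapped symbols, fewer than ``min_mgs`` MGS genes
    remain — small MGSs carry too little context for a meaningful test.
    """
    if gene not in mgs.genes:
        raise ValueError(f"gene {gene!r} is not mutated in sample {mgs.sample!r}")
    if gene not in net:
        return None
    rest, _ = mapped_members(net, mgs.genes - {gene})
    if len(rest) < min_mgs:
        return None
    return nea_gene_vs_set(
        net, gene, rest, mode=mode, ensemble=ensemble, target_name=f"MGS:{mgs.sample}"
    )


def test_cna_vs_mgs(
    net: GeneNetwork,
    gene: str,
    mgs_map: Mapping[str, Mgs],
    calls: Iterable[CnaCall],
    ensemble: NullEnsemble,
    mode: str = "direct",
    min_mgs: int = MIN_MGS_SIZE,
) -> tuple[dict[str, NeaResult], CombinedPValue | None]:
    """1CNA-vs-MGS: a copy-number-altered gene against the point-mutation MGS
    of each genome that carries the alteration.

    Per-genome one-sided p-values are combined by Fisher's method
    (df = 2 * number of usable carrier genomes). Returns (per-genome results,
    combined) with combined None when no carrier genome has a usable MGS.
    """
    if gene not in net:
        return {}, None
    per_genome: dict[str, NeaResult] = {}
    for call in calls:
        if call.gene != gene or call.sample in per_genome:
            continue
        mgs = mgs_map.get(call.sample)
        if mgs is None:
            continue
        rest, _ = mapped_members(net, mgs.genes - {gene})
        if len(rest) < min_mgs:
            continue
        per_genome[call.sample] = nea_gene_vs_set(
            net, gene, rest, mode=mode, ensemble=ensemble,
            target_name=f"MGS:{call.sample}",
        )
    if not per_genome:
        return per_genome, None
    combined = fisher_combine([r.p for r in per_genome.values()])
    return per_genome, combined


def test_vs_cpw(
    net: GeneNetwork,
    gene: str,
    collection: PathwayCollection,
    cfg: CpwConfig | None = None,
    ensemble: NullEnsemble | None = None,
    mode: str = "direct",
) -> tuple[float, float, bool]:
    """1-vs-CPW: one gene against the cancer pathway collection.

    ``sum_all_CAN`` sums the per-pathway z-scores over every CAN set and
    divides by the normalization factor (the CAN sets overlap heavily, so
    their z-scores are strongly correlated and the naive sum overstates
    significance). ``superpathway_only`` tests against the designated
    super-pathway alone. Returns (normalized z, one-sided p, significance at
    the z cutoff).
    """
    cfg = cfg or CpwConfig()
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    can = collection.can_sets()
    if not can:
        raise ValueError("pathway collection has no CAN sets")
    if cfg.mode == "superpathway_only":
        if collection.superpathway is None:
            raise ValueError("no super-pathway designated in the collection")
        res = nea_gene_vs_set(
            net, gene, collection.sets[collection.superpathway], mode=mode,
            ensemble=ensemble, target_name=collection.superpathway,
        )
        return res.z, res.p, res.z >= cfg.z_cutoff
    if cfg.mode != "sum_all_CAN":
        raise ValueError(f"unknown CPW mode {cfg.mode!r}")
    z_sum = 0.0
    n_used = 0
    for name, genes in can.items():
        members, _ = mapped_members(net, genes)
        members.discard(gene)
        if not members:
            continue
        res = nea_gene_vs_set(net, gene, members, mode=mode, ensemble=ensemble, target_name=name)
        z = max(0.0, res.z) if cfg.floor_negative else res.z
        z_sum += z
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no CAN set maps to the network for gene {gene!r}")
    z_star = cfg.normalize(z_sum)
    return z_star, z_to_p(z_star), z_star >= cfg.z_cutoff


def cooccurrence_scan(
    candidate_carriers: Mapping[str, set[str]],
    point_carriers: Mapping[str, set[str]],
    samples: Iterable[str],
    alpha: float = COOC_ALPHA,
) -> dict[str, CoocResult]:
    """Screen candidate genes for co-occurrence with point mutations.

    For each (candidate, point-mutated gene) pair of distinct genes, a 2x2
    table over the common sample universe (both / candidate only / partner
    only / neither) is tested one-sided by Fisher's exact test. A candidate
    passes the screen iff its minimum raw p is below ``alpha``; the reported
    ``p_co`` is the Bonferroni-corrected minimum over tested partners.
    """
    universe = set(samples)
    if len(universe) < 2:
        raise ValueError("co-occurrence needs at least 2 samples")
    out: dict[str, CoocResult] = {}
    for gene, carriers in candidate_carriers.items():
        carriers = carriers & universe
        min_p, best = 1.0, None
        n_tested = 0
        for partner, p_carr in point_carriers.items():
            if partner == gene:
                continue  # positional self-pair, not informative
            p_carr = p_carr & universe
            a = len(carriers & p_carr)
            b = len(p_carr) - a
            c = len(carriers) - a
            d = len(universe) - a - b - c
            p = fisher_exact_2x2(a, b, c, d, sided="one")
            n_tested += 1
            if p < min_p:
                min_p, best = p, partner
        p_co = min(1.0, min_p * n_tested) if n_tested else 1.0
        out[gene] = CoocResult(
            gene=gene, n_partners_tested=n_tested, min_p=min_p,
            best_partner=best, p_co=p_co, passes=n_tested > 0 and min_p < alpha,
        )
    return out


# -- combination and calling -----------------------------------------------


def _combine_available(ps: list[float | None]) -> CombinedPValue:
    avail = [p for p in ps if p is not None and not (isinstance(p, float) and math.isnan(p))]
    if not avail:
        raise ValueError("no available p-value components to combine")
    return fisher_combine(avail)


def combine_point(p_mgs: float | None, p_cpw: float | None) -> CombinedPValue:
    """Combine the 1point-vs-MGS and 1-vs-CPW p-values for one point event.

    A skipped component (None) is dropped and the degrees of freedom shrink
    accordingly; with one component the combined p equals it.
    """
    return _combine_available([p_mgs, p_cpw])


def combine_cna(
    p_co: float | None, p_mgs_combined: float | None, p_cpw: float | None
) -> CombinedPValue:
    """Combine co-occurrence, combined 1CNA-vs-MGS and 1-vs-CPW p-values for
    one copy-number-altered gene."""
    return _combine_available([p_co, p_mgs_combined, p_cpw])


def rank_and_adjust(
    scores: list[CombinedScore],
    method: str = "fdr_bh",
    threshold: float = DRIVER_THRESHOLD,
) -> list[CombinedScore]:
    """BH-adjust combined p-values within one event class and call drivers.

    Events are sorted by combined p; an event is called a driver iff its
    adjusted p is strictly below ``threshold``. The combined values are a
    ranking device; the adjusted threshold supplies the confidence gate.
    """
    if not scores:
        raise ValueError("no scored events to rank")
    ps = np.array([s.combined_p for s in scores])
    _, adj, _, _ = multipletests(ps, method=method)
    for s, a in zip(scores, adj):
        s.adjusted_p = float(a)
        s.driver_call = bool(a < threshold)
    return sorted(scores, key=lambda s: (s.combined_p, s.event_id))


# -- orchestration ---------------------------------------------------------


@dataclass
class PipelineResult:
    point_events: pd.DataFrame
    cna_genes: pd.DataFrame
    gene_track: pd.DataFrame
    coherence: pd.DataFrame


def _scores_to_frame(scores: list[CombinedScore], extra: dict[str, dict]) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {
            "event_id": s.event_id,
            "gene": s.gene,
            "sample": s.sample if s.sample is not None else "",
            "p_mgs": s.p_mgs,
            "p_cpw": s.p_cpw,
            "p_co": s.p_co,
            "chi2": s.chi2,
            "df": s.df,
            "combined_p": s.combined_p,
            "adjusted_p": s.adjusted_p,
            "driver_call": s.driver_call,
        }
        row.update(extra.get(s.event_id, {}))
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    net: GeneNetwork,
    maf_records: list[MutationRecord],
    collection: PathwayCollection,
    cna_profile: pd.DataFrame | None = None,
    n_rand: int = N_RANDOMIZATIONS,
    seed: int = 0,
    rewire_cfg: RewireConfig | None = None,
    cpw_cfg: CpwConfig | None = None,
    mode: str = "direct",
    tau: float = CNA_TAU,
    min_genomes: int = CNA_MIN_GENOMES,
    alpha_co: float = COOC_ALPHA,
    fdr_threshold: float = DRIVER_THRESHOLD,
    coherence: bool = True,
) -> PipelineResult:
    """Run the full prioritization over a cohort.

    Builds one rewired-replica ensemble for the network, scores every point
    mutation event (1point-vs-MGS + 1-vs-CPW) and every eligible CNA gene
    (co-occurrence screen + combined 1CNA-vs-MGS + 1-vs-CPW), combines and
    BH-adjusts within each event class, and reports per-event tables plus a
    per-gene -log10 combined-p track.
    """
    cpw_cfg = cpw_cfg or CpwConfig()
    ensemble = NullEnsemble.for_network(net, n_rand=n_rand, seed=seed, rewire_cfg=rewire_cfg)
    mgs_map = build_mgs(maf_records)

    # per-gene 1-vs-CPW (cached: one test per distinct mapped gene)
    cpw_cache: dict[str, tuple[float, float, bool]] = {}

    def cpw(gene: str):
        if gene not in cpw_cache:
            cpw_cache[gene] = test_vs_cpw(net, gene, collection, cpw_cfg, ensemble, mode=mode)
        return cpw_cache[gene]

    # -- point events
    point_scores: list[CombinedScore] = []
    point_extra: dict[str, dict] = {}
    unmapped_rows = []
    for sample in sorted(mgs_map):
        mgs = mgs_map[sample]
        for gene in sorted(mgs.genes):
            event_id = f"PM:{sample}:{gene}"
            if gene not in net:
                unmapped_rows.append({"event_id": event_id, "gene": gene, "sample": sample})
                continue
            res = test_point_vs_mgs(net, mgs, gene, ensemble, mode=mode)
            p_mgs = res.p if res is not None else None
            z_star, p_cpw, sig = cpw(gene)
            comb = combine_point(p_mgs, p_cpw)
            point_scores.append(
                CombinedScore(
                    event_id=event_id, gene=gene, sample=sample,
                    p_mgs=p_mgs, p_cpw=p_cpw, p_co=None,
                    chi2=comb.chi2, df=comb.df, combined_p=comb.p,
                )
            )
            point_extra[event_id] = {
                "n_iG": res.observed if res is not None else np.nan,
                "z_mgs": res.z if res is not None else np.nan,
                "z_cpw_norm": z_star,
                "cpw_significant": sig,
            }
    if point_scores:
        point_scores = rank_and_adjust(point_scores, threshold=fdr_threshold)
    point_df = _scores_to_frame(point_scores, point_extra)
    if unmapped_rows:
        logger.info("%d point event(s) on genes absent from the network", len(unmapped_rows))
        point_df = pd.concat([point_df, pd.DataFrame(unmapped_rows)], ignore_index=True)

    # -- per-sample MGS coherence (reported, not part of driver calling)
    coh_rows = []
    if coherence:
        for sample in sorted(mgs_map):
            members, _ = mapped_members(net, mgs_map[sample].genes)
            if len(members) < MIN_MGS_SIZE:
                continue
            res = nea_set_coherence(net, members, mode=mode, ensemble=ensemble, set_name=sample)
            coh_rows.append(
                {
                    "sample": sample, "n_genes": len(members),
                    "observed": res.observed, "null_mean": res.null_mean,
                    "null_sd": res.null_sd, "z": res.z, "p": res.p,
                }
            )
    coherence_df = pd.DataFrame(coh_rows)

    # -- CNA genes
    cna_scores: list[CombinedScore] = []
    cna_extra: dict[str, dict] = {}
    screened_out = []
    if cna_profile is not None:
        calls, eligible = call_cna(cna_profile, tau=tau, min_genomes=min_genomes)
        carriers: dict[str, set[str]] = {}
        for call in calls:
            carriers.setdefault(call.gene, set()).add(call.sample)
        point_carriers = {}
        for sample, mgs in mgs_map.items():
            for gene in mgs.genes:
                point_carriers.setdefault(gene, set()).add(sample)
        universe = set(cna_profile.columns.astype(str)) | set(mgs_map)
        cooc = cooccurrence_scan(
            {g: carriers[g] for g in eligible}, point_carriers, universe, alpha=alpha_co
        )
        for gene in eligible:
            event_id = f"CNA:{gene}"
            screen = cooc[gene]
            if not screen.passes or gene not in net:
                screened_out.append(
                    {
                        "event_id": event_id, "gene": gene, "sample": "",
                        "p_co": screen.p_co, "cooc_min_p": screen.min_p,
                        "cooc_partner": screen.best_partner or "",
                        "n_carrier_genomes": len(carriers[gene]),
                        "driver_call": False,
                    }
                )
                continue
            per_genome, comb_mgs = test_cna_vs_mgs(
                net, gene, mgs_map, calls, ensemble, mode=mode
            )
            p_mgs = comb_mgs.p if comb_mgs is not None else None
            z_star, p_cpw, sig = cpw(gene)
            comb = combine_cna(screen.p_co, p_mgs, p_cpw)
            cna_scores.append(
                CombinedScore(
                    event_id=event_id, gene=gene, sample=None,
                    p_mgs=p_mgs, p_cpw=p_cpw, p_co=screen.p_co,
                    chi2=comb.chi2, df=comb.df, combined_p=comb.p,
                )
            )
            cna_extra[event_id] = {
                "n_carrier_genomes": len(carriers[gene]),
                "n_own_mgs": len(per_genome),
                "cooc_min_p": screen.min_p,
                "cooc_partner": screen.best_partner or "",
                "z_cpw_norm": z_star,
                "cpw_significant": sig,
            }
        if cna_scores:
            cna_scores = rank_and_adjust(cna_scores, threshold=fdr_threshold)
    cna_df = _scores_to_frame(cna_scores, cna_extra)
    if screened_out:
        cna_df = pd.concat([cna_df, pd.DataFrame(screened_out)], ignore_index=True)

    # -- per-gene track: best combined p over all events of the gene
    best: dict[str, float] = {}
    for s in point_scores + cna_scores:
        best[s.gene] = min(best.get(s.gene, 1.0), s.combined_p)
    track = pd.DataFrame(
        {
            "gene": sorted(best),
            "neg_log10_combined_p": [-math.log10(max(best[g], P_FLOOR_TRACK)) for g in sorted(best)],
        }
    )
    return PipelineResult(
        point_events=point_df, cna_genes=cna_df, gene_track=track, coherence=coherence_df
    )


P_FLOOR_TRACK = 1e-300


def write_pipeline_result(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.point_events.to_csv(out / "point_events.tsv", sep="\t", index=False)
    result.cna_genes.to_csv(out / "cna_genes.tsv", sep="\t", index=False)
    result.gene_track.to_csv(out / "gene_track.tsv", sep="\t", index=False)
    result.coherence.to_csv(out / "mgs_coherence.tsv", sep="\t", index=False)
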