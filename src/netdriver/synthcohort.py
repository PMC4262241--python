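"""Synthetic cohorts with known driver/passenger ground truth.

Generates the four inputs the pipeline consumes — a global network, a
pathway collection, a per-sample mutation table and a gene x sample
copy-number matrix — with planted structure that mirrors the statistical
assumptions of network enrichment analysis: driver genes cluster inside
dense pathway-like network modules and co-occur within genomes, passengers
fall uniformly on the rest of the network, and copy-number events hit
contiguous chromosomal segments in which exactly one gene (the planted CNA
driver) belongs to a module.

The generator targets this statistical structure, not realistic tumor
mutation spectra: no mutational signatures, subclonality or purity effects.

Default scenario: 1000-node Barabási–Albert network (heavy-tailed degrees,
as in real functional-coupling networks), 5 planted modules of 15 genes with
intra-module edge probability 0.6, 50 samples with 5 drivers + 20 passengers
each, one planted CNA driver per module carried by 5 genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .driverscan import MutationRecord, PathwayCollection
from .graphnet import GeneNetwork, write_edge_list

logger = logging.getLogger("netdriver")

__all__ = [
    "SyntheticTruth",
    "SyntheticScenario",
    "DEFAULT_PRESET",
    "gen_network",
    "plant_modules",
    "gen_cohort",
    "gen_cna_profiles",
    "generate_scenario",
    "write_scenario",
]

SUPERPATHWAY_NAME = "CAN_SUPER"


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent RNG stream derived from the master seed and a label."""
    entropy = [seed] + [ord(c) for c in stream]
    return np.random.default_rng(np.random.SeedSequence(entropy=entropy))


@dataclass
class SyntheticTruth:
    """Planted ground truth behind one synthetic scenario."""

    network: GeneNetwork
    modules: PathwayCollection
    point_driver_labels: set[tuple[str, str]] = field(default_factory=set)  # (sample, gene)
    cna_driver_genes: set[str] = field(default_factory=set)
    params: dict = field(default_factory=dict)


@dataclass
class SyntheticScenario:
    """A fully generated cohort plus its ground truth."""

    truth: SyntheticTruth
    maf_records: list[MutationRecord]
    point_labels: pd.DataFrame  # sample, gene, label (driver|passenger)
    cna_profile: pd.DataFrame | None = None
    cna_labels: pd.DataFrame | None = None  # gene, segment, label


def gen_network(
    n_nodes: int = 1000,
    mean_degree: float = 6.0,
    model: str = "BA",
    seed: int = 0,
) -> GeneNetwork:
    """Random background network with gene-symbol node names G000001...

    ``ER`` draws a fixed-edge-count Erdős–Rényi graph; ``BA`` grows a
    Barabási–Albert graph (attachment parameter m = mean_degree / 2) whose
    degree distribution is heavy-tailed like real interactomes.
    """
    if n_nodes < 10:
        raise ValueError("need at least 10 nodes")
    if mean_degree < 2:
        raise ValueError("mean_degree must be >= 2")
    rng_seed = int(_stream_rng(seed, f"net-{model}").integers(0, 2**31))
    if model == "ER":
        m_edges = int(round(n_nodes * mean_degree / 2))
        g = nx.gnm_random_graph(n_nodes, m_edges, seed=rng_seed)
    elif model == "BA":
        g = nx.barabasi_albert_graph(n_nodes, max(1, int(round(mean_degree / 2))), seed=rng_seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    mapping = {k: f"G{k + 1:06d}" for k in g.nodes()}
    return GeneNetwork.from_networkx(nx.relabel_nodes(g, mapping))


def plant_modules(
    net: GeneNetwork,
    k_modules: int = 5,
    module_size: int = 15,
    p_intra: float = 0.6,
    seed: int = 0,
) -> tuple[GeneNetwork, PathwayCollection]:
    """Plant dense pathway-like modules into a network.

    Disjoint member sets are drawn uniformly; every absent intra-module edge
    is added with probability ``p_intra`` (existing edges kept). The module
    collection is tagged CAN, with a union super-pathway, so it doubles as
    the cancer-pathway collection of the 1-vs-CPW test.
    """
    if k_modules * module_size > len(net):
        raise ValueError("modules do not fit into the network")
    if not 0 < p_intra <= 1:
        raise ValueError("p_intra must be in (0, 1]")
    rng = _stream_rng(seed, "modules")
    nodes = sorted(net.nodes)
    picked = rng.choice(len(nodes), size=k_modules * module_size, replace=False)
    adj = {g: set(nb) for g, nb in net._adj.items()}
    sets: dict[str, frozenset[str]] = {}
    categories: dict[str, str] = {}
    for m in range(k_modules):
        members = sorted(nodes[i] for i in picked[m * module_size : (m + 1) * module_size])
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                u, v = members[a], members[b]
                if v not in adj[u] and rng.random() < p_intra:
                    adj[u].add(v)
                    adj[v].add(u)
        name = f"MODULE_{m + 1:02d}"
        sets[name] = frozenset(members)
        categories[name] = "CAN"
    union = frozenset().union(*sets.values())
    sets[SUPERPATHWAY_NAME] = union
    categories[SUPERPATHWAY_NAME] = "CAN"
    collection = PathwayCollection(sets=sets, categories=categories, superpathway=SUPERPATHWAY_NAME)
    return GeneNetwork(adj), collection


def gen_cohort(
    truth: SyntheticTruth,
    n_samples: int = 50,
    drivers_per_sample: int = 5,
    passengers_per_sample: int = 20,
    n_small_mgs_samples: int = 0,
    seed: int = 0,
) -> tuple[list[MutationRecord], pd.DataFrame]:
    """Per-sample mutated gene sets with labelled drivers and passengers.

    Each sample draws its drivers from one or two planted modules (tumors
    perturb a small number of pathways) and its passengers uniformly from
    non-module genes. Optional extra samples carry a single module driver
    plus one passenger — mutated gene sets too small for the genome-local
    test, exercising the pathway-based rescue route.
    """
    if drivers_per_sample < 0 or passengers_per_sample < 0:
        raise ValueError("per-sample rates must be non-negative")
    rng = _stream_rng(seed, "cohort")
    module_names = [n for n in sorted(truth.modules.sets) if n != SUPERPATHWAY_NAME]
    module_genes = sorted(frozenset().union(*(truth.modules.sets[n] for n in module_names)))
    background = sorted(truth.network.nodes - set(module_genes))
    records: list[MutationRecord] = []
    labels = []

    def emit(sample: str, gene: str, label: str) -> None:
        records.append(MutationRecord(sample=sample, gene=gene, variant_classification="Missense_Mutation"))
        labels.append({"sample": sample, "gene": gene, "label": label})
        if label == "driver":
            truth.point_driver_labels.add((sample, gene))

    for s in range(n_samples):
        sample = f"S{s + 1:04d}"
        n_mods = int(rng.integers(1, 3))  # one or two perturbed pathways
        mods = rng.choice(len(module_names), size=n_mods, replace=False)
        pool = sorted(frozenset().union(*(truth.modules.sets[module_names[m]] for m in mods)))
        k = min(drivers_per_sample, len(pool))
        for i in rng.choice(len(pool), size=k, replace=False):
            emit(sample, pool[i], "driver")
        for i in rng.choice(len(background), size=min(passengers_per_sample, len(background)), replace=False):
            emit(sample, background[i], "passenger")
    for s in range(n_small_mgs_samples):
        sample = f"T{s + 1:04d}"
        m = module_names[int(rng.integers(0, len(module_names)))]
        pool = sorted(truth.modules.sets[m])
        emit(sample, pool[int(rng.integers(0, len(pool)))], "driver")
        emit(sample, background[int(rng.integers(0, len(background)))], "passenger")
    return records, pd.DataFrame(labels)


def gen_cna_profiles(
    truth: SyntheticTruth,
    samples: list[str],
    segment_length: int = 8,
    amplitude: float = 0.6,
    noise_sd: float = 0.1,
    carriers_per_driver: int = 5,
    partner_mutations: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[MutationRecord]]:
    """Gene x sample log2 copy-number matrix with planted driver segments.

    Genes are laid out on a synthetic chromosome (lexicographic order). For
    each planted module, one member becomes a CNA driver; a contiguous
    segment of ``segment_length`` genes around it — the driver plus
    module-external chromosomal neighbours — is shifted by ±``amplitude`` in
    each carrier genome, on top of Gaussian measurement noise everywhere.
    Carrier genomes additionally receive point mutations in partners from the
    driver's module, so CNA–point co-occurrence is detectable. Returns the
    matrix, per-gene segment labels (driver vs passenger-in-segment), and the
    extra point-mutation records to append to the cohort.
    """
    if segment_length < 3:
        raise ValueError("segment_length must be >= 3")
    if abs(amplitude) <= 0.35:
        logger.info(
            "planted amplitude %.3g does not exceed the default 0.35 call "
            "threshold; segments will not be callable at that threshold",
            amplitude,
        )
    rng = _stream_rng(seed, "cna")
    chromosome = sorted(truth.network.nodes)
    position = {g: i for i, g in enumerate(chromosome)}
    module_names = [n for n in sorted(truth.modules.sets) if n != SUPERPATHWAY_NAME]
    all_module_genes = frozenset().union(*(truth.modules.sets[n] for n in module_names))

    matrix = rng.normal(0.0, noise_sd, size=(len(chromosome), len(samples)))
    label_rows = []
    extra_records: list[MutationRecord] = []
    used_positions: set[int] = set()
    for m_idx, name in enumerate(module_names):
        members = sorted(truth.modules.sets[name])
        driver = members[int(rng.integers(0, len(members)))]
        truth.cna_driver_genes.add(driver)
        # contiguous segment: the driver plus nearest module-external genes
        segment = [driver]
        left = right = position[driver]
        while len(segment) < segment_length:
            left -= 1
            right += 1
            for pos in (left, right):
                if 0 <= pos < len(chromosome) and len(segment) < segment_length:
                    g = chromosome[pos]
                    if g not in all_module_genes and pos not in used_positions:
                        segment.append(g)
        used_positions.update(position[g] for g in segment)
        carriers = rng.choice(len(samples), size=min(carriers_per_driver, len(samples)), replace=False)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        rows = [position[g] for g in segment]
        for c in carriers:
            matrix[np.ix_(rows, [c])] += sign * amplitude
            partners = [g for g in members if g != driver]
            k = min(partner_mutations, len(partners))
            for i in rng.choice(len(partners), size=k, replace=False):
                extra_records.append(
                    MutationRecord(
                        sample=samples[c], gene=partners[i],
                        variant_classification="Missense_Mutation",
                    )
                )
        for g in segment:
            label_rows.append(
                {
                    "gene": g,
                    "segment": f"SEG_{m_idx + 1:02d}",
                    "label": "cna_driver" if g == driver else "cna_passenger",
                }
            )
    profile = pd.DataFrame(matrix, index=chromosome, columns=samples)
    return profile, pd.DataFrame(label_rows), extra_records


DEFAULT_PRESET = dict(
    n_nodes=1000,
    mean_degree=6.0,
    model="BA",
    k_modules=5,
    module_size=15,
    p_intra=0.6,
    n_samples=50,
    drivers_per_sample=5,
    passengers_per_sample=20,
    n_small_mgs_samples=0,
    with_cna=True,
    segment_length=8,
    amplitude=0.6,
    noise_sd=0.1,
    carriers_per_driver=5,
)


def generate_scenario(seed: int = 0, **overrides) -> SyntheticScenario:
    """Generate a complete labelled scenario from the default preset."""
    params = dict(DEFAULT_PRESET)
    unknown = set(overrides) - set(params)
    if unknown:
        raise TypeError(f"unknown scenario parameters: {sorted(unknown)}")
    params.update(overrides)
    base = gen_network(params["n_nodes"], params["mean_degree"], params["model"], seed=seed)
    net, collection = plant_modules(
        base, params["k_modules"], params["module_size"], params["p_intra"], seed=seed
    )
    truth = SyntheticTruth(network=net, modules=collection, params={**params, "seed": seed})
    records, point_labels = gen_cohort(
        truth,
        n_samples=params["n_samples"],
        drivers_per_sample=params["drivers_per_sample"],
        passengers_per_sample=params["passengers_per_sample"],
        n_small_mgs_samples=params["n_small_mgs_samples"],
        seed=seed,
    )
    cna_profile = cna_labels = None
    if params["with_cna"]:
        samples = sorted({r.sample for r in records})
        cna_profile, cna_labels, extra = gen_cna_profiles(
            truth,
            samples,
            segment_length=params["segment_length"],
            amplitude=params["amplitude"],
            noise_sd=params["noise_sd"],
            carriers_per_driver=params["carriers_per_driver"],
            seed=seed,
        )
        records = records + extra
    return SyntheticScenario(
        truth=truth,
        maf_records=records,
        point_labels=point_labels,
        cna_profile=cna_profile,
        cna_labels=cna_labels,
    )


def write_scenario(scenario: SyntheticScenario, out_dir) -> dict[str, Path]:
    """Write a scenario as the pipeline's file formats.

    Produces a network edge list, a GMT + category manifest, a MAF, a CNA
    log2 TSV and label tables; every file round-trips through the
    corresponding reader.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["network"] = out / "network.tsv"
    write_edge_list(scenario.truth.network, paths["network"])

    paths["gmt"] = out / "pathways.gmt"
    with open(paths["gmt"], "wt") as fh:
        for name in sorted(scenario.truth.modules.sets):
            genes = sorted(scenario.truth.modules.sets[name])
            fh.write("\t".join([name, "synthetic module"] + genes) + "\n")
    paths["categories"] = out / "categories.tsv"
    with open(paths["categories"], "wt") as fh:
        for name in sorted(scenario.truth.modules.sets):
            cat = scenario.truth.modules.categories.get(name, "OTH")
            marker = "\tsuperpathway" if name == scenario.truth.modules.superpathway else ""
            fh.write(f"{name}\t{cat}{marker}\n")

    paths["maf"] = out / "mutations.maf"
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": [r.gene for r in scenario.maf_records],
            "Tumor_Sample_Barcode": [r.sample for r in scenario.maf_records],
            "Variant_Classification": [r.variant_classification for r in scenario.maf_records],
        }
    )
    maf.to_csv(paths["maf"], sep="\t", index=False)

    paths["point_labels"] = out / "point_labels.tsv"
    scenario.point_labels.to_csv(paths["point_labels"], sep="\t", index=False)

    if scenario.cna_profile is not None:
        paths["cna"] = out / "cna_log2.tsv"
        scenario.cna_profile.to_csv(paths["cna"], sep="\t")
        paths["cna_labels"] = out / "cna_labels.tsv"
        scenario.cna_labels.to_csv(paths["cna_labels"], sep="\t", index=False)
    return paths
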