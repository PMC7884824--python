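"""Seeded synthetic fixtures for every pipeline stage.

Each generator plants known structure (true adducts, source drugs, hub
centers, an enriched gene set, expression folds) and returns a truth map so
downstream recovery tests are self-checking.  Each generator draws from its
own RNG stream, derived from the master seed by a stable label, so adding a
generator never shifts another's output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .masslib import (
    DEFAULT_ADDUCTS,
    AdductRule,
    CompoundRecord,
    MolecularFormula,
    Peak,
    adduct_mz,
)
from .netfilter import InteractionEdge
from .qpcr import CtMeasurement
from .targetmap import DrugRecord, Fingerprint

__all__ = [
    "SimConfig",
    "gen_ms_fixture",
    "gen_target_fixture",
    "gen_network_fixture",
    "gen_enrichment_fixture",
    "gen_qpcr_fixture",
    "write_all_fixtures",
]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # MS fixture
    n_compounds: int = 100
    c_range: tuple[int, int] = (4, 30)
    h_per_c: tuple[float, float] = (0.8, 2.2)
    o_range: tuple[int, int] = (0, 10)
    n_range: tuple[int, int] = (0, 3)
    ppm_sigma: float = 2.0
    # target fixture
    fp_length: int = 1024
    fp_density: float = 0.1
    flip_rate: float = 0.05
    n_drugs: int = 50
    targets_per_drug: tuple[int, int] = (2, 6)
    n_genes: int = 300
    # network fixture
    net_nodes: int = 400
    background_mean_degree: float = 4.0
    n_planted_hubs: int = 10
    hub_degree: int = 40
    low_conf_fraction: float = 0.3
    target_fraction: float = 0.5
    # enrichment fixture
    n_sets: int = 20
    set_size: tuple[int, int] = (10, 50)
    universe_size: int = 1000
    query_size: int = 40
    enrichment_rate: float = 0.5
    # qPCR fixture
    qpcr_genes: tuple[str, ...] = ("GENE1", "GENE2", "GENE3", "GENE4")
    qpcr_groups: tuple[str, ...] = ("control", "model", "treated")
    group_size: int = 6
    planted_folds: Optional[dict] = None  # (group, gene) -> fold; default 1.0
    ct_sigma: float = 0.1
    ref_gene: str = "REF"

    def rng(self, label: str) -> np.random.Generator:
        """Independent stream keyed by (seed, label)."""
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])


# ---------------------------------------------------------------------------
# MS fixture


def gen_ms_fixture(
    cfg: SimConfig, rules: Sequence[AdductRule] = DEFAULT_ADDUCTS
) -> tuple[list[CompoundRecord], list[Peak], dict[int, tuple[str, str]]]:
    """Compound library + one peak per compound at a noisy true adduct m/z.

    The truth map is peak index -> (compound id, adduct name).
    """
    rng = cfg.rng("ms")
    library: list[CompoundRecord] = []
    seen: set[str] = set()
    while len(library) < cfg.n_compounds:
        c = int(rng.integers(cfg.c_range[0], cfg.c_range[1] + 1))
        h = max(1, int(round(c * rng.uniform(*cfg.h_per_c))))
        o = int(rng.integers(cfg.o_range[0], cfg.o_range[1] + 1))
        n = int(rng.integers(cfg.n_range[0], cfg.n_range[1] + 1))
        counts = {"C": c, "H": h}
        if o:
            counts["O"] = o
        if n:
            counts["N"] = n
        formula = MolecularFormula(counts)
        key = formula.hill()
        if key in seen:  # distinct formulas keep annotation unambiguous
            continue
        seen.add(key)
        i = len(library)
        library.append(CompoundRecord(f"CPD{i:04d}", f"compound-{i}", formula))

    peaks: list[Peak] = []
    truth: dict[int, tuple[str, str]] = {}
    for i, comp in enumerate(library):
        rule = rules[int(rng.integers(len(rules)))]
        mz = adduct_mz(comp.formula, rule)
        noisy = mz * (1.0 + rng.normal(0.0, cfg.ppm_sigma) * 1e-6)
        rt = float(np.round(rng.uniform(0.5, 20.0), 2))
        peaks.append(Peak(rt_min=rt, mz=noisy, polarity=rule.polarity))
        truth[i] = (comp.id, rule.name)
    return library, peaks, truth


# ---------------------------------------------------------------------------
# Target fixture


def _random_bits(rng: np.random.Generator, length: int, density: float) -> frozenset[int]:
    mask = rng.random(length) < density
    return frozenset(int(i) for i in np.flatnonzero(mask))


def gen_target_fixture(
    cfg: SimConfig,
) -> tuple[list[DrugRecord], list[Fingerprint], dict[str, str]]:
    """Drug library + query fingerprints that are bit-flipped drug prints.

    The truth map is query compound id -> source drug id.
    """
    rng = cfg.rng("target")
    gene_pool = [f"G{i:04d}" for i in range(cfg.n_genes)]
    drugs: list[DrugRecord] = []
    for i in range(cfg.n_drugs):
        bits = _random_bits(rng, cfg.fp_length, cfg.fp_density)
        k = int(rng.integers(cfg.targets_per_drug[0], cfg.targets_per_drug[1] + 1))
        targets = frozenset(rng.choice(gene_pool, size=k, replace=False).tolist())
        drugs.append(DrugRecord(f"DRUG{i:03d}", Fingerprint(f"DRUG{i:03d}", bits, cfg.fp_length), targets))

    queries: list[Fingerprint] = []
    truth: dict[str, str] = {}
    for i, drug in enumerate(drugs):
        flips = rng.random(cfg.fp_length) < cfg.flip_rate
        bits = set(drug.fingerprint.bits)
        for idx in np.flatnonzero(flips):
            idx = int(idx)
            if idx in bits:
                bits.discard(idx)
            else:
                bits.add(idx)
        qid = f"Q{i:03d}"
        queries.append(Fingerprint(qid, frozenset(bits), cfg.fp_length))
        truth[qid] = drug.drug_id
    return drugs, queries, truth


# ---------------------------------------------------------------------------
# Network fixture


def gen_network_fixture(
    cfg: SimConfig,
) -> tuple[list[InteractionEdge], dict[str, str], list[str]]:
    """Erdos-Renyi background plus overlay stars on planted hub centers.

    Returns (edge list with confidences, node -> role map, planted hub list).
    A ``low_conf_fraction`` of edges receives a confidence below 0.4 so the
    confidence filter has work to do.
    """
    rng = cfg.rng("network")
    n = cfg.net_nodes
    nodes = [f"N{i:04d}" for i in range(n)]
    p_bg = cfg.background_mean_degree / max(n - 1, 1)

    edge_set: set[tuple[str, str]] = set()
    upper = rng.random((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if upper[i, j] < p_bg:
                edge_set.add((nodes[i], nodes[j]))

    hub_idx = rng.choice(n, size=cfg.n_planted_hubs, replace=False)
    planted = [nodes[int(i)] for i in hub_idx]
    for h in hub_idx:
        others = [j for j in range(n) if j != h]
        spokes = rng.choice(len(others), size=cfg.hub_degree, replace=False)
        for s in spokes:
            j = others[int(s)]
            a, b = sorted((int(h), j))
            edge_set.add((nodes[a], nodes[b]))

    edges: list[InteractionEdge] = []
    for a, b in sorted(edge_set):
        if rng.random() < cfg.low_conf_fraction:
            conf = float(rng.uniform(0.0, 0.4 - 1e-9))
        else:
            conf = float(rng.uniform(0.4, 1.0))
        edges.append(InteractionEdge(a, b, conf))

    roles: dict[str, str] = {}
    for node in nodes:
        r = rng.random()
        if r < cfg.target_fraction * 0.8:
            roles[node] = "putative_target"
        elif r < cfg.target_fraction:
            roles[node] = "both"
        else:
            roles[node] = "disease_gene"
    return edges, roles, planted


# ---------------------------------------------------------------------------
# Enrichment fixture


def gen_enrichment_fixture(
    cfg: SimConfig,
) -> tuple[list[tuple[str, str, frozenset[str]]], set[str], str]:
    """GMT-style collection + query with one set sampled at elevated rate.

    Returns (sets as (name, description, genes), query gene set, planted set
    name).  With ``enrichment_rate`` 0 the query is a uniform draw from the
    universe and the planted set behaves like any other.
    """
    rng = cfg.rng("enrich")
    universe = [f"U{i:05d}" for i in range(cfg.universe_size)]
    sets = []
    for i in range(cfg.n_sets):
        size = int(rng.integers(cfg.set_size[0], cfg.set_size[1] + 1))
        genes = frozenset(rng.choice(universe, size=size, replace=False).tolist())
        sets.append((f"SET{i:03d}", f"synthetic set {i}", genes))
    planted_name = sets[int(rng.integers(cfg.n_sets))][0]
    planted_genes = sorted(next(g for nm, _, g in sets if nm == planted_name))

    query: set[str] = set()
    while len(query) < cfg.query_size:
        if rng.random() < cfg.enrichment_rate:
            query.add(str(rng.choice(planted_genes)))
        else:
            query.add(str(rng.choice(universe)))
    return sets, query, planted_name


# ---------------------------------------------------------------------------
# qPCR fixture


def gen_qpcr_fixture(cfg: SimConfig) -> tuple[list[CtMeasurement], dict]:
    """Ct table with planted fold changes relative to the control group.

    Target-gene Ct = baseline - log2(fold) + noise; the truth map records the
    planted fold per (group, gene).
    """
    rng = cfg.rng("qpcr")
    folds = dict(cfg.planted_folds or {})
    measurements: list[CtMeasurement] = []
    truth: dict = {}
    baseline_ref = 15.0
    for group in cfg.qpcr_groups:
        for s in range(cfg.group_size):
            sample = f"{group}_{s}"
            for rep in (1, 2, 3):
                noise = float(rng.normal(0.0, cfg.ct_sigma))
                measurements.append(
                    CtMeasurement(sample, group, cfg.ref_gene, baseline_ref + noise, rep)
                )
            for gene in cfg.qpcr_genes:
                fold = float(folds.get((group, gene), 1.0))
                truth[f"{group}|{gene}"] = fold
                base = 22.0 - np.log2(fold)
                for rep in (1, 2, 3):
                    noise = float(rng.normal(0.0, cfg.ct_sigma))
                    measurements.append(
                        CtMeasurement(sample, group, gene, float(base + noise), rep)
                    )
    return measurements, truth


# ---------------------------------------------------------------------------
# On-disk fixture bundles (exactly the formats the pipeline reads)


def write_all_fixtures(cfg: SimConfig, out_dir) -> dict[str, Path]:
    """Write every fixture plus its truth JSON; returns name -> path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    library, peaks, ms_truth = gen_ms_fixture(cfg)
    p = out / "compound_library.tsv"
    with open(p, "w") as fh:
        fh.write("id\tname\tformula\tsource\n")
        for c in library:
            fh.write(f"{c.id}\t{c.name}\t{c.formula.hill()}\tsynthetic\n")
    paths["compound_library"] = p
    p = out / "peaks.csv"
    with open(p, "w") as fh:
        fh.write("rt_min,mz,polarity\n")
        for pk in peaks:
            fh.write(f"{pk.rt_min},{pk.mz:.6f},{pk.polarity}\n")
    paths["peaks"] = p
    p = out / "ms_truth.json"
    p.write_text(json.dumps({str(k): v for k, v in ms_truth.items()}, indent=1))
    paths["ms_truth"] = p

    drugs, queries, tg_truth = gen_target_fixture(cfg)
    p = out / "drug_library.tsv"
    with open(p, "w") as fh:
        fh.write("drug_id\tbits\ttargets\n")
        for d in drugs:
            bits = ",".join(map(str, sorted(d.fingerprint.bits)))
            fh.write(f"{d.drug_id}\t{bits}\t{';'.join(sorted(d.targets))}\n")
    paths["drug_library"] = p
    p = out / "query_fingerprints.tsv"
    with open(p, "w") as fh:
        fh.write(f"#length={cfg.fp_length}\n")
        for q in queries:
            bits = ",".join(map(str, sorted(q.bits)))
            fh.write(f"{q.compound_id}\t{bits}\n")
    paths["query_fingerprints"] = p
    p = out / "target_truth.json"
    p.write_text(json.dumps(tg_truth, indent=1))
    paths["target_truth"] = p

    edges, roles, planted = gen_network_fixture(cfg)
    p = out / "edges.tsv"
    with open(p, "w") as fh:
        fh.write("node_a\tnode_b\tcombined_score\n")
        for e in edges:
            fh.write(f"{e.a}\t{e.b}\t{e.confidence:.4f}\n")
    paths["edges"] = p
    p = out / "roles.tsv"
    with open(p, "w") as fh:
        fh.write("node\trole\n")
        for node, role in sorted(roles.items()):
            fh.write(f"{node}\t{role}\n")
    paths["roles"] = p
    p = out / "network_truth.json"
    p.write_text(json.dumps({"planted_hubs": planted}, indent=1))
    paths["network_truth"] = p

    sets, query, planted_name = gen_enrichment_fixture(cfg)
    p = out / "pathways.gmt"
    with open(p, "w") as fh:
        for name, desc, genes in sets:
            fh.write(name + "\t" + desc + "\t" + "\t".join(sorted(genes)) + "\n")
    paths["gmt"] = p
    p = out / "query_genes.txt"
    p.write_text("\n".join(sorted(query)) + "\n")
    paths["query_genes"] = p
    p = out / "enrichment_truth.json"
    p.write_text(json.dumps({"planted_set": planted_name}, indent=1))
    paths["enrichment_truth"] = p

    cts, qp_truth = gen_qpcr_fixture(cfg)
    p = out / "ct_table.csv"
    with open(p, "w") as fh:
        fh.write("sample,group,gene,ct,replicate\n")
        for m in cts:
            fh.write(f"{m.sample},{m.group},{m.gene},{m.ct:.4f},{m.replicate}\n")
    paths["ct_table"] = p
    p = out / "qpcr_truth.json"
    p.write_text(json.dumps(qp_truth, indent=1))
    paths["qpcr_truth"] = p

    return paths
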