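"""Fingerprint similarity and drug->target transfer.

Query compounds are compared against an approved-drug library by Tanimoto
(Jaccard) similarity of binary fingerprints; targets of every drug at or
above the similarity threshold (default 0.8) are transferred to the query.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Fingerprint",
    "DrugRecord",
    "TargetPrediction",
    "tanimoto",
    "predict_targets",
    "aggregate_targets",
    "read_fingerprints",
    "read_drug_library",
    "write_predictions",
]


@dataclass(frozen=True)
class Fingerprint:
    """A set of set-bit indices, optionally with a declared length."""

    compound_id: str
    bits: frozenset[int]
    length: Optional[int] = None

    def __post_init__(self) -> None:
        bits = frozenset(self.bits)
        if any(b < 0 for b in bits):
            raise ValueError("bit indices must be non-negative")
        if self.length is not None and any(b >= self.length for b in bits):
            raise ValueError("bit index exceeds declared fingerprint length")
        object.__setattr__(self, "bits", bits)


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    fingerprint: Fingerprint
    targets: frozenset[str]

    def __post_init__(self) -> None:
        targets = frozenset(t.upper() for t in self.targets)
        if not targets:
            raise ValueError(f"drug {self.drug_id!r} has no targets")
        object.__setattr__(self, "targets", targets)


@dataclass(frozen=True)
class TargetPrediction:
    compound_id: str
    gene: str
    supporting_drugs: tuple[str, ...]
    max_similarity: float


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Jaccard similarity |a & b| / |a | b| of two bit sets.

    Two empty fingerprints carry no structural evidence, so the similarity is
    defined as 0.0 (with a warning) rather than 1.0.
    """
    if not a.bits and not b.bits:
        warnings.warn("tanimoto of two empty fingerprints defined as 0.0")
        return 0.0
    inter = len(a.bits & b.bits)
    union = len(a.bits | b.bits)
    return inter / union


def predict_targets(
    query: Fingerprint,
    library: Sequence[DrugRecord],
    threshold: float = 0.8,
) -> list[TargetPrediction]:
    """Transfer targets of all drugs with tanimoto >= threshold (inclusive).

    One prediction per (query, gene), with supporting drugs aggregated and the
    maximum similarity over them recorded.  Sorted by gene for determinism.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if not library:
        warnings.warn("empty drug library: no predictions possible")
        return []
    per_gene: dict[str, tuple[list[str], float]] = {}
    for drug in library:
        sim = tanimoto(query, drug.fingerprint)
        if sim >= threshold:
            for gene in drug.targets:
                drugs, best = per_gene.get(gene, ([], 0.0))
                drugs.append(drug.drug_id)
                per_gene[gene] = (drugs, max(best, sim))
    return [
        TargetPrediction(query.compound_id, gene, tuple(sorted(drugs)), best)
        for gene, (drugs, best) in sorted(per_gene.items())
    ]


def aggregate_targets(
    predictions: Iterable[TargetPrediction],
) -> dict[str, set[str]]:
    """Deduplicated union of predicted targets across compounds.

    Returns gene -> set of compound ids that predict it (provenance).
    """
    provenance: dict[str, set[str]] = {}
    for pred in predictions:
        provenance.setdefault(pred.gene, set()).add(pred.compound_id)
    return provenance


# ---------------------------------------------------------------------------
# File formats

def _data_lines(path):
    with open(path, newline="") as fh:
        return [ln for ln in fh if not ln.startswith("#")]


def _parse_bits(text: str) -> frozenset[int]:
    text = text.strip()
    if not text:
        return frozenset()
    return frozenset(int(tok) for tok in text.split(","))


def read_fingerprints(path) -> list[Fingerprint]:
    """Read a fingerprint TSV: id <tab> comma-separated bit indices.

    An optional header line ``#length=N`` declares the fingerprint length.
    """
    length: Optional[int] = None
    prints = []
    with open(path, newline="") as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln:
                continue
            if ln.startswith("#"):
                if ln.startswith("#length="):
                    length = int(ln.split("=", 1)[1])
                continue
            cid, _, bits = ln.partition("\t")
            prints.append(Fingerprint(cid, _parse_bits(bits), length))
    return prints


def read_drug_library(path) -> list[DrugRecord]:
    """Read a drug library TSV: drug_id, bit indices, ';'-separated genes."""
    lib = []
    for ln in _data_lines(path):
        ln = ln.rstrip("\n")
        if not ln or ln.startswith("drug_id\t"):
            continue
        drug_id, bits, genes = ln.split("\t")
        lib.append(
            DrugRecord(
                drug_id=drug_id,
                fingerprint=Fingerprint(drug_id, _parse_bits(bits)),
                targets=frozenset(g for g in genes.split(";") if g),
            )
        )
    return lib


def write_predictions(
    predictions: Sequence[TargetPrediction], path, header_comment: str = ""
) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["compound_id", "gene", "max_similarity", "supporting_drugs"])
        for p in predictions:
            w.writerow(
                [p.compound_id, p.gene, f"{p.max_similarity:.4f}", ";".join(p.supporting_drugs)]
            )
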