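"""Relative expression by the 2^-ddCt (Livak) method.

Technical replicates are averaged on the Ct scale, dCt is taken against a
reference gene per sample, ddCt against the mean dCt of the control group,
and fold change is 2^-ddCt.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CtMeasurement",
    "RelativeExpression",
    "relative_expression",
    "group_summary",
    "read_ct_table",
    "write_expression",
]


@dataclass(frozen=True)
class CtMeasurement:
    sample: str
    group: str
    gene: str
    ct: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not (self.ct > 0 and math.isfinite(self.ct)):
            raise ValueError(f"Ct must be positive and finite: {self.ct}")


@dataclass(frozen=True)
class RelativeExpression:
    sample: str
    group: str
    gene: str
    dct: float
    ddct: float
    fold: float


def relative_expression(
    measurements: Sequence[CtMeasurement],
    ref_gene: str,
    control_group: str,
) -> list[RelativeExpression]:
    """Per-sample fold changes for every non-reference gene.

    dCt = mean Ct(gene) - mean Ct(ref) within a sample; ddCt = dCt minus the
    control-group mean dCt for that gene; fold = 2^-ddCt.
    """
    if not measurements:
        raise ValueError("no Ct measurements")
    df = pd.DataFrame(
        [(m.sample, m.group, m.gene, m.ct) for m in measurements],
        columns=["sample", "group", "gene", "ct"],
    )
    mean_ct = df.groupby(["sample", "group", "gene"], as_index=False)["ct"].mean()
    ref = mean_ct[mean_ct["gene"] == ref_gene].set_index("sample")["ct"]
    missing = set(mean_ct["sample"]) - set(ref.index)
    if missing:
        raise ValueError(
            f"reference gene {ref_gene!r} missing for samples: {sorted(missing)}"
        )
    genes = mean_ct[mean_ct["gene"] != ref_gene].copy()
    genes["dct"] = genes["ct"] - genes["sample"].map(ref).astype(float)
    if control_group not in set(genes["group"]):
        raise ValueError(f"unknown control group {control_group!r}")
    control_mean = (
        genes[genes["group"] == control_group].groupby("gene")["dct"].mean()
    )
    genes["ddct"] = genes["dct"] - genes["gene"].map(control_mean).astype(float)
    genes["fold"] = 2.0 ** (-genes["ddct"])
    return [
        RelativeExpression(r.sample, r.group, r.gene, r.dct, r.ddct, r.fold)
        for r in genes.itertuples(index=False)
    ]


def group_summary(expressions: Iterable[RelativeExpression]) -> pd.DataFrame:
    """Mean and SD of fold change per (group, gene)."""
    df = pd.DataFrame(
        [(e.group, e.gene, e.fold) for e in expressions],
        columns=["group", "gene", "fold"],
    )
    return (
        df.groupby(["group", "gene"])["fold"]
        .agg(mean_fold="mean", sd_fold="std", n="count")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# File formats

def read_ct_table(path) -> list[CtMeasurement]:
    """Read a Ct CSV with columns sample, group, gene, ct[, replicate]."""
    out = []
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    for row in csv.DictReader(lines):
        out.append(
            CtMeasurement(
                sample=row["sample"],
                group=row["group"],
                gene=row["gene"],
                ct=float(row["ct"]),
                replicate=int(row.get("replicate") or 1),
            )
        )
    return out


def write_expression(
    expressions: Sequence[RelativeExpression], path, header_comment: str = ""
) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        w = csv.writer(fh)
        w.writerow(["sample", "group", "gene", "dCt", "ddCt", "fold"])
        for e in expressions:
            w.writerow(
                [e.sample, e.group, e.gene, f"{e.dct:.4f}", f"{e.ddct:.4f}", f"{e.fold:.4f}"]
            )
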