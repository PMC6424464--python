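"""Map localized residues to annotated binding-site clusters and report.

Cluster definitions are a plain-TSV annotation (protein_id, start, end,
cluster_id, cluster_name, note); the shipped table reproduces the three
neurosteroid-site clusters of the alpha1/beta3 receptor study — the
beta3(+)/alpha1(-) intersubunit site, the alpha1 intrasubunit site and the
beta3 intrasubunit site — so other receptors or annotations can reuse the
pipeline by swapping the file.  Assignment is a pure sequence-coordinate
lookup; no structural computation is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .localize import LocalizationResult

__all__ = [
    "SiteAnnotation",
    "ReportRow",
    "load_annotations",
    "default_annotations",
    "assign_cluster",
    "render_report",
]


@dataclass(frozen=True)
class SiteAnnotation:
    protein_id: str
    start: int
    end: int
    cluster_id: int
    cluster_name: str
    note: str = ""

    def overlaps(self, protein_id: str, interval: tuple[int, int]) -> bool:
        return (
            protein_id == self.protein_id
            and interval[0] <= self.end
            and interval[1] >= self.start
        )


@dataclass
class ReportRow:
    reagent: str
    protein_id: str
    peptide: str
    interval: tuple[int, int]
    cluster: str  # cluster id as text, "unassigned", or "ambiguous:<ids>"
    cluster_name: str = ""
    efficiency_pct: float | None = None
    efficiency_sd: float | None = None
    n: int | None = None
    competition_reduction_pct: float | None = None


def load_annotations(path) -> list[SiteAnnotation]:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "start", "end", "cluster_id", "cluster_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        dup = [
            a for a in out
            if a.overlaps(str(row["protein_id"]), (int(row["start"]), int(row["end"])))
        ]
        if any(a.cluster_id != int(row["cluster_id"]) for a in dup):
            raise ValueError(
                f"residue range {row['protein_id']}:{row['start']}-{row['end']} "
                "maps to more than one cluster"
            )
        out.append(
            SiteAnnotation(
                str(row["protein_id"]), int(row["start"]), int(row["end"]),
                int(row["cluster_id"]), str(row["cluster_name"]),
                str(row.get("note", "") or ""),
            )
        )
    return out


def default_annotations() -> list[SiteAnnotation]:
    """The shipped alpha1/beta3 three-cluster annotation."""
    path = resources.files("photosite").joinpath("data/gabaa_site_clusters.tsv")
    with resources.as_file(path) as p:
        return load_annotations(p)


def assign_cluster(
    result: LocalizationResult | tuple[str, tuple[int, int]],
    annotations: list[SiteAnnotation],
) -> tuple[str, str]:
    """(cluster label, cluster name) for a localized interval.

    Label is the cluster id as text, ``"unassigned"`` when no annotated
    residue intersects, or ``"ambiguous:<id,id>"`` when several clusters do.
    """
    if isinstance(result, LocalizationResult):
        protein_id, interval = result.peptide.protein_id, result.interval
    else:
        protein_id, interval = result
    hits = sorted(
        {(a.cluster_id, a.cluster_name) for a in annotations if a.overlaps(protein_id, interval)}
    )
    if not hits:
        return "unassigned", ""
    if len(hits) == 1:
        return str(hits[0][0]), hits[0][1]
    return "ambiguous:" + ",".join(str(c) for c, _ in hits), "; ".join(n for _, n in hits)


_COLUMNS = [
    "reagent", "protein_id", "peptide", "interval_start", "interval_end",
    "cluster", "cluster_name", "efficiency_pct", "efficiency_sd", "n",
    "competition_reduction_pct",
]


def _row_record(r: ReportRow) -> dict:
    fmt = lambda v: None if v is None else round(float(v), 4)  # noqa: E731
    return {
        "reagent": r.reagent,
        "protein_id": r.protein_id,
        "peptide": r.peptide,
        "interval_start": r.interval[0],
        "interval_end": r.interval[1],
        "cluster": r.cluster,
        "cluster_name": r.cluster_name,
        "efficiency_pct": fmt(r.efficiency_pct),
        "efficiency_sd": fmt(r.efficiency_sd),
        "n": r.n,
        "competition_reduction_pct": fmt(r.competition_reduction_pct),
    }


def render_report(rows: list[ReportRow], fmt: str = "tsv") -> str:
    """Deterministic report (ordered by protein, position) in tsv/json/markdown."""
    if fmt not in ("tsv", "json", "markdown"):
        raise ValueError(f"unknown report format {fmt!r}")
    ordered = sorted(rows, key=lambda r: (r.protein_id, r.interval, r.reagent))
    records = [_row_record(r) for r in ordered]
    if fmt == "json":
        return json.dumps(records, indent=1)
    if fmt == "tsv":
        lines = ["\t".join(_COLUMNS)]
        for rec in records:
            lines.append("\t".join("" if rec[c] is None else str(rec[c]) for c in _COLUMNS))
        return "\n".join(lines) + "\n"
    # markdown
    lines = ["| " + " | ".join(_COLUMNS) + " |", "|" + "---|" * len(_COLUMNS)]
    for rec in records:
        lines.append(
            "| " + " | ".join("" if rec[c] is None else str(rec[c]) for c in _COLUMNS) + " |"
        )
    return "\n".join(lines) + "\n"
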