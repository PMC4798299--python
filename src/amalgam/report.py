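"""Writers for the toolkit's summary tables.

All reports are plain TSV with a comment header recording the tool version,
a configuration hash and the seed, so a report can always be traced back to
the run that produced it. Every derived cell (totals, holes filled) is
recomputed from its component cells at render time — nothing is cached.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .duplication import DuplicationCandidate
from .matching import AUTO_CRITERIA, MatchCriterion, MatchSet
from .pgdb import DIST_BUCKETS, HoleReport


def config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(seed: int | None, config: Mapping | None) -> str:
    return (
        f"# amalgam v{__version__}\tconfig_hash={config_hash(config)}"
        f"\tseed={'' if seed is None else seed}\n"
    )


def _write(df: pd.DataFrame, path: str | Path | None, seed, config) -> str:
    text = _header(seed, config) + df.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def render_table1(
    match_set: MatchSet,
    path: str | Path | None = None,
    seed: int | None = None,
    config: Mapping | None = None,
) -> pd.DataFrame:
    """Per-criterion match counts: non-exclusive vs sequential, plus Total."""
    rows = []
    for c in AUTO_CRITERIA:
        rows.append(
            {
                "criterion": c.label,
                "nonexclusive": match_set.per_criterion_nonexclusive.get(c, 0),
                "sequential": match_set.per_criterion_sequential.get(c, 0),
            }
        )
    rows.append(
        {
            "criterion": MatchCriterion.MANUAL.label,
            "nonexclusive": 0,
            "sequential": match_set.per_criterion_sequential.get(MatchCriterion.MANUAL, 0),
        }
    )
    rows.append(
        {
            "criterion": "Total",
            "nonexclusive": sum(r["nonexclusive"] for r in rows),
            "sequential": sum(r["sequential"] for r in rows),
        }
    )
    df = pd.DataFrame(rows, columns=["criterion", "nonexclusive", "sequential"])
    _write(df, path, seed, config)
    return df


def render_table2(
    counts: Mapping[str, int],
    path: str | Path | None = None,
    seed: int | None = None,
    config: Mapping | None = None,
) -> pd.DataFrame:
    """Amalgamated-database category counts plus their recomputed total."""
    order = ["consensus", "a_only", "b_only", "scaffold"]
    rows = [{"category": k, "genes": counts.get(k, 0)} for k in order]
    rows.append({"category": "Total", "genes": sum(r["genes"] for r in rows)})
    df = pd.DataFrame(rows, columns=["category", "genes"])
    _write(df, path, seed, config)
    return df


def render_table3(
    initial: HoleReport,
    curated: HoleReport,
    path: str | Path | None = None,
    seed: int | None = None,
    config: Mapping | None = None,
) -> pd.DataFrame:
    """Initial-vs-curated hole accounting, including holes filled."""
    import logging

    if curated.total_holes > initial.total_holes:
        logging.getLogger(__name__).warning(
            "curation added holes (%d -> %d)", initial.total_holes, curated.total_holes
        )

    def col(r: HoleReport) -> list:
        return (
            [len(r.holes_per_pathway), r.total_holes, round(r.pct_holes, 1)]
            + [r.distribution[b] for b in DIST_BUCKETS]
            + [r.pathways_with_holes]
        )

    labels = (
        ["Metabolic pathways", "Number of pathway holes", "Holes as % of reactions in pathways"]
        + [
            "Pathways with no holes",
            "Pathways with 1 hole",
            "Pathways with 2 holes",
            "Pathways with 3 holes",
            "Pathways with 4 holes",
            "Pathways with >4 holes",
        ]
        + ["Total pathways with holes"]
    )
    df = pd.DataFrame({"statistic": labels, "initial": col(initial), "curated": col(curated)})
    filled = initial.total_holes - curated.total_holes
    df.loc[len(df)] = ["Pathway holes filled", filled, filled]
    _write(df, path, seed, config)
    return df


def render_table4(
    candidates: Sequence[DuplicationCandidate],
    path: str | Path | None = None,
    seed: int | None = None,
    config: Mapping | None = None,
) -> pd.DataFrame:
    """One row per gene copy: locus, rank, mechanism, pathway annotations."""
    rows = []
    for cand in candidates:
        for copy in cand.copies:
            rows.append(
                {
                    "gene": cand.anchor_gene_id,
                    "copy_id": copy.gene_id,
                    "chrom": copy.chrom or "",
                    "start": "" if copy.start is None else copy.start,
                    "end": "" if copy.end is None else copy.end,
                    "pathways": ", ".join(sorted(cand.pathways)),
                    "rank": cand.rank or "",
                    "mechanism": cand.mechanism or "",
                    "is_metabolic": int(cand.is_metabolic),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "copy_id", "chrom", "start", "end",
            "pathways", "rank", "mechanism", "is_metabolic",
        ],
    )
    _write(df, path, seed, config)
    return df
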