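"""Report writers: score-sorted TSV, lossless JSON, and oligo FASTA.

Coordinates in reports are 1-based inclusive (wet-lab convention);
everything internal stays 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .pipeline import TargetResult

TSV_COLUMNS = [
    "target", "rank", "ligation_pos_1based", "hybrid_start_1based",
    "hybrid_end_1based", "lhs", "rhs", "lhs_len", "rhs_len",
    "s_tm", "s_dg", "s_gc", "s_lig", "adenosine_adjusted", "final_score",
    "tm_lhs", "tm_rhs", "gc_lhs", "gc_rhs",
    "unique_locus", "n_variant_overlaps",
    "lpo", "rpo", "amplicon_len",
    "ms_pass", "ms_enzyme", "ms_site_1based",
]


def _rows(res: TargetResult, view: str = "genomic") -> list[dict]:
    rows = res.ranked if view == "genomic" else (res.ms_view or [])
    out = []
    for rank, r in enumerate(rows, start=1):
        c = r.candidate
        verdict = r.ms_verdict
        locus = (
            f"{r.locus[0]}:{r.locus[1] + 1}:{r.locus[2]}" if r.locus else ""
        )
        out.append(
            {
                "target": c.target_id,
                "rank": rank,
                "ligation_pos_1based": c.ligation_pos + 1,
                "hybrid_start_1based": c.start + 1,
                "hybrid_end_1based": c.start + len(c.hybrid),
                "lhs": c.lhs,
                "rhs": c.rhs,
                "lhs_len": len(c.lhs),
                "rhs_len": len(c.rhs),
                "s_tm": round(r.breakdown.s_tm, 6),
                "s_dg": round(r.breakdown.s_dg, 6),
                "s_gc": round(r.breakdown.s_gc, 6),
                "s_lig": r.breakdown.s_lig,
                "adenosine_adjusted": r.breakdown.adenosine_adjusted,
                "final_score": round(r.breakdown.final, 6),
                "tm_lhs": round(r.breakdown.metrics.get("tm_lhs", float("nan")), 2),
                "tm_rhs": round(r.breakdown.metrics.get("tm_rhs", float("nan")), 2),
                "gc_lhs": round(r.breakdown.metrics.get("gc_lhs", float("nan")), 4),
                "gc_rhs": round(r.breakdown.metrics.get("gc_rhs", float("nan")), 4),
                "unique_locus": locus,
                "n_variant_overlaps": len(r.variant_overlaps),
                "lpo": r.oligos.lpo,
                "rpo": r.oligos.rpo,
                "amplicon_len": r.oligos.amplicon_len,
                "ms_pass": "" if verdict is None else verdict.passed,
                "ms_enzyme": verdict.site.enzyme if verdict and verdict.site else "",
                "ms_site_1based": (
                    verdict.site.position + 1 if verdict and verdict.site else ""
                ),
            }
        )
    return out


def write_tsv(results: list[TargetResult], path: str | Path, view: str = "genomic") -> None:
    rows = [row for res in results for row in _rows(res, view)]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def write_failed_tsv(results: list[TargetResult], path: str | Path) -> None:
    """Failed probe sets and the workflow step at which each failed."""
    rows = []
    for res in results:
        for f in res.failed:
            rows.append(
                {
                    "target": f.candidate.target_id,
                    "ligation_pos_1based": f.candidate.ligation_pos + 1,
                    "lhs_len": len(f.candidate.lhs),
                    "rhs_len": len(f.candidate.rhs),
                    "failed_step": f.step,
                    "reasons": "; ".join(f.reasons),
                }
            )
    pd.DataFrame(
        rows,
        columns=["target", "ligation_pos_1based", "lhs_len", "rhs_len",
                 "failed_step", "reasons"],
    ).to_csv(path, sep="\t", index=False)


def write_json(results: list[TargetResult], path: str | Path) -> None:
    """Lossless JSON superset of the TSV report."""
    payload = []
    for res in results:
        payload.append(
            {
                "target": res.target.id,
                "n_ranked": len(res.ranked),
                "n_failed": len(res.failed),
                "probe_sets": _rows(res, "genomic"),
                "ms_view": None if res.ms_view is None else _rows(res, "ms"),
                "failed": [
                    {
                        "ligation_pos_1based": f.candidate.ligation_pos + 1,
                        "lhs_len": len(f.candidate.lhs),
                        "rhs_len": len(f.candidate.rhs),
                        "step": f.step,
                        "reasons": f.reasons,
                    }
                    for f in res.failed
                ],
            }
        )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def oligo_fasta_header(target: str, ligation_pos: int, score: float, which: str) -> str:
    return f"{target}|lig={ligation_pos + 1}|score={score:.6f}|{which}"


def parse_oligo_header(header: str) -> tuple[str, int, float, str]:
    target, lig, score, which = header.split("|")
    return (
        target,
        int(lig.removeprefix("lig=")) - 1,
        float(score.removeprefix("score=")),
        which,
    )


def write_oligo_fasta(results: list[TargetResult], path: str | Path, view: str = "genomic") -> None:
    with open(path, "w") as fh:
        for res in results:
            rows = res.ranked if view == "genomic" else (res.ms_view or [])
            for r in rows:
                c = r.candidate
                for which, seq in (("LPO", r.oligos.lpo), ("RPO", r.oligos.rpo)):
                    hdr = oligo_fasta_header(
                        c.target_id, c.ligation_pos, r.breakdown.final, which
                    )
                    fh.write(f">{hdr}\n{seq}\n")


def write_all(results: list[TargetResult], out_dir: str | Path, ms: bool = False) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tsv": out_dir / "probe_sets.tsv",
        "failed": out_dir / "failed_probe_sets.tsv",
        "json": out_dir / "probe_sets.json",
        "fasta": out_dir / "oligos.fa",
    }
    write_tsv(results, paths["tsv"])
    write_failed_tsv(results, paths["failed"])
    write_json(results, paths["json"])
    write_oligo_fasta(results, paths["fasta"])
    if ms:
        paths["ms_tsv"] = out_dir / "probe_sets_msmlpa.tsv"
        write_tsv(results, paths["ms_tsv"], view="ms")
    return paths
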