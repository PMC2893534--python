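"""MS-MLPA restriction-enzyme filtering.

In methylation-specific MLPA the probe-target hybrid must contain a site
for a methylation-sensitive restriction enzyme: unmethylated copies are
digested and yield no amplicon, methylated copies survive. A candidate
probe set is admissible only when all four rules hold:

1. exactly one recognition site in the hybridizing sequences (LHS+RHS) —
   with more than one it is impossible to tell which site was digested;
2. no extra recognition sites anywhere in the assembled LPO or RPO — some
   of these enzymes nick single-stranded DNA at a low rate, and an extra
   site in a primer/stuffer junction would add error to a methylation
   frequency estimate;
3. at least 4 hybridizing nt between each end of the site and the nearer
   outer end of the probe-target hybrid — digestion is less efficient near
   the end of the double-stranded region;
4. no known SNP inside the recognition site — a polymorphism there changes
   digestion and mimics a methylation difference.

Rule 1 is counted on the concatenated LHS+RHS, so a site spanning the
ligation nick counts as one site (the hybrid is contiguous on the target);
this interpretation is flagged in reports.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .seq_core import reverse_complement
from .uniqueness import VariantOverlap

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class RestrictionEnzyme:
    name: str
    recognition: str  # IUPAC, 5'->3' top strand
    cut_offset_top: int
    cut_offset_bottom: int
    methylation_sensitive: bool

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


@dataclass(frozen=True)
class SiteHit:
    position: int  # 0-based start of the matched footprint
    strand: str  # '+' or '-'
    enzyme: str

    def footprint(self, site_len: int) -> tuple[int, int]:
        return (self.position, self.position + site_len)


@dataclass
class MsFilterVerdict:
    """Outcome of the four-rule filter; passes iff every rule passes."""

    rule_results: dict[int, bool]
    site: SiteHit | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.rule_results.values())


class EnzymeTableError(ValueError):
    pass


def _cg_count(recognition: str) -> int:
    """Overlapping count of CpG dinucleotides in the literal recognition."""
    return sum(
        1 for i in range(len(recognition) - 1) if recognition[i : i + 2] == "CG"
    )


def validate_enzyme_table(table: list[RestrictionEnzyme]) -> list[RestrictionEnzyme]:
    """Reject entries violating type-II/within-site/CpG-count admissibility.

    Only type II enzymes cleaving strictly inside their recognition
    sequence are usable, and a methylation-sensitive recognition must carry
    exactly one CpG (multiple CpGs make partial methylation ambiguous).
    """
    problems = []
    names = set()
    for e in table:
        if e.name in names:
            raise EnzymeTableError(f"duplicate enzyme name {e.name!r}")
        names.add(e.name)
        bad = set(e.recognition) - set(IUPAC_EXPAND)
        if bad:
            problems.append(f"{e.name}: non-IUPAC characters {sorted(bad)}")
            continue
        n = len(e.recognition)
        for off in (e.cut_offset_top, e.cut_offset_bottom):
            if not (1 <= off <= n - 1):
                problems.append(
                    f"{e.name}: cut offset {off} not inside the recognition site"
                )
        if e.methylation_sensitive:
            cg = _cg_count(e.recognition)
            if cg == 0:
                problems.append(f"{e.name}: methylation-sensitive but no CpG")
            elif cg > 1:
                problems.append(f"{e.name}: multiple CpG dinucleotides ({cg})")
    if problems:
        raise EnzymeTableError("; ".join(problems))
    return list(table)


def load_enzyme_table(path: str | Path | None = None) -> list[RestrictionEnzyme]:
    """Load and validate the packaged (or a user-supplied) enzyme TSV."""
    if path is None:
        text = resources.files("mlpaprobe.data").joinpath("enzymes.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("name\t"):
            continue
        name, recog, top, bottom, ms = line.split("\t")
        table.append(
            RestrictionEnzyme(
                name=name,
                recognition=recog.upper(),
                cut_offset_top=int(top),
                cut_offset_bottom=int(bottom),
                methylation_sensitive=ms.strip().lower() in ("true", "1", "yes"),
            )
        )
    return validate_enzyme_table(table)


def get_enzyme(name: str, table: list[RestrictionEnzyme] | None = None) -> RestrictionEnzyme:
    table = table if table is not None else load_enzyme_table()
    for e in table:
        if e.name == name:
            return e
    raise KeyError(f"enzyme {name!r} not in table")


def _iupac_regex(recognition: str) -> re.Pattern:
    body = "".join(
        c if len(IUPAC_EXPAND[c]) == 1 else f"[{IUPAC_EXPAND[c]}]"
        for c in recognition
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def find_sites(seq: str, enzyme: RestrictionEnzyme) -> list[SiteHit]:
    """Every recognition-site match in ``seq``, overlapping matches included.

    The top strand is scanned with the IUPAC-expanded recognition; for
    non-palindromic recognitions the reverse complement is scanned too
    (reported with strand '-'); palindromic sites are reported once.
    """
    hits = [
        SiteHit(m.start(), "+", enzyme.name)
        for m in _iupac_regex(enzyme.recognition).finditer(seq)
    ]
    if not enzyme.is_palindromic:
        rc = reverse_complement(enzyme.recognition)
        hits += [
            SiteHit(m.start(), "-", enzyme.name)
            for m in _iupac_regex(rc).finditer(seq)
        ]
    return sorted(hits, key=lambda h: (h.position, h.strand))


MIN_FLANK = 4  # nt of hybridizing sequence required on each side of the site


def ms_filter(
    cand,
    oligos,
    enzyme: RestrictionEnzyme,
    variant_overlaps: list[VariantOverlap] | None = None,
    include_indels: bool = False,
) -> MsFilterVerdict:
    """Apply the four MS-MLPA rules to a candidate with assembled oligos.

    ``variant_overlaps`` is the output of the variation test (hybrid-local
    coordinates); by default only SNP-kind variants count under rule 4.
    """
    if not enzyme.methylation_sensitive:
        raise ValueError(f"{enzyme.name} is not methylation-sensitive")
    hybrid = cand.hybrid
    site_len = len(enzyme.recognition)
    hybrid_hits = find_sites(hybrid, enzyme)
    notes = []

    rule1 = len(hybrid_hits) == 1

    # Rule 2: sites in the full single-stranded LPO and RPO must be exactly
    # those attributable to the hybrid site(s); any extra site created by a
    # primer/stuffer/tag union fails.
    expected = 0
    lhs_len = len(cand.lhs)
    for h in hybrid_hits:
        s, e = h.footprint(site_len)
        if e <= lhs_len or s >= lhs_len:
            expected += 1  # fully inside one half -> appears in that oligo
        else:
            notes.append("site spans the ligation nick (counted once, rule 1)")
    observed = len(find_sites(oligos.lpo, enzyme)) + len(find_sites(oligos.rpo, enzyme))
    rule2 = observed == expected

    # Rule 3: >= MIN_FLANK hybridizing nt between each site edge and the
    # nearer outer end of the hybrid (the nick is not an end).
    rule3 = True
    for h in hybrid_hits:
        s, e = h.footprint(site_len)
        if s < MIN_FLANK or len(hybrid) - e < MIN_FLANK:
            rule3 = False

    # Rule 4: no variant inside the recognition-site footprint.
    rule4 = True
    for h in hybrid_hits:
        s, e = h.footprint(site_len)
        for ov in variant_overlaps or []:
            if ov.variant.kind != "SNP" and not include_indels:
                continue
            if ov.hybrid_start < e and ov.hybrid_end > s:
                rule4 = False

    verdict = MsFilterVerdict(
        rule_results={1: rule1, 2: rule2, 3: rule3, 4: rule4},
        notes=notes,
    )
    if verdict.passed:
        verdict.site = hybrid_hits[0]
    return verdict


def apply_ms_view(ranked_rows, enzyme: RestrictionEnzyme):
    """Filter ranked result rows to MS-MLPA survivors, order preserved.

    Each row must expose ``candidate``, ``oligos`` and ``variant_overlaps``;
    the verdict is attached as ``row.ms_verdict``. Survivors are the subset
    passing :func:`ms_filter`; the score order is never changed.
    """
    survivors = []
    for row in ranked_rows:
        verdict = ms_filter(row.candidate, row.oligos, enzyme, row.variant_overlaps)
        row.ms_verdict = verdict
        if verdict.passed:
            survivors.append(row)
    return survivors
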