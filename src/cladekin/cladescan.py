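"""Clade-discriminating residue scan (specificity-determining positions).

The screen combines two filters over an aligned protein family split into
taxonomic clades (orders):

1. *reference-unique*: the reference sequence carries a residue found in
   no other sequence at that column;
2. *clade-discriminating*: a chosen target clade is highly conserved at
   the column, and its consensus residue differs from the consensus of
   every contrast clade.

A column passing both is a candidate determinant of a clade-specific
property (here, sensitivity to allosteric inhibitors), reported at the
reference sequence's ungapped position so it can name a mutagenesis
target.  The aliphatic index is included as the standard sequence-level
thermostability proxy used when comparing such family members.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .errors import DataError
from .seq_core import AMINO_ACIDS, GAP_CHAR, Alignment

# fixed ordering used for deterministic consensus tie-breaks
_AA_ORDER = {aa: i for i, aa in enumerate(sorted(AMINO_ACIDS))}


@dataclass
class ScanParams:
    """Parameters of the discriminating-position filter.

    other_gap_policy:
      "mismatch"  -- a gapped row counts as differing from the reference
                     and stays in consensus denominators (default);
      "ignore"    -- gapped rows are dropped from the comparison and from
                     consensus denominators.
    strict_contrast: require the target consensus residue to be absent
      from every contrast-clade member, not merely different from each
      contrast consensus.
    """

    target_clade: str
    contrast_clades: list[str]
    conservation_threshold: float = 0.9
    other_gap_policy: str = "mismatch"
    strict_contrast: bool = False

    def __post_init__(self):
        if not 0.0 < self.conservation_threshold <= 1.0:
            raise DataError("conservation_threshold must be in (0, 1]")
        if self.target_clade in self.contrast_clades:
            raise DataError("target_clade cannot also be a contrast clade")
        if self.other_gap_policy not in ("mismatch", "ignore"):
            raise DataError("other_gap_policy must be 'mismatch' or 'ignore'")


@dataclass
class CandidateSite:
    column: int
    reference_position: int
    reference_residue: str
    clade_consensus: dict[str, tuple[str | None, float]] = field(default_factory=dict)
    passes: list[str] = field(default_factory=list)


@dataclass
class KnownSiteReport:
    reference_position: int
    column: int
    reference_residue: str
    clade_consensus: dict[str, tuple[str | None, float]]
    conserved_in_all: bool


def _clade_members(alignment: Alignment, clade: str) -> list[str]:
    members = [sid for sid, c in alignment.clade_map.items() if c == clade]
    if not members:
        raise DataError(f"clade {clade!r} has no members in the alignment")
    # keep alignment order for determinism
    order = {sid: i for i, sid in enumerate(alignment.ids)}
    return sorted(members, key=order.__getitem__)


def clade_consensus(
    alignment: Alignment, clade: str, column: int, other_gap_policy: str = "mismatch"
) -> tuple[str | None, float]:
    """Modal non-gap, non-X residue of the clade at `column` and its
    frequency.  Ties break toward the alphabetically earlier amino acid.

    Under the "mismatch" policy the denominator is the full clade size
    (gaps dilute conservation); under "ignore" it is the number of
    ungapped members.  Returns (None, 0.0) when nothing is countable.
    """
    members = _clade_members(alignment, clade)
    residues = [alignment.sequence(m).residues[column - 1] for m in members]
    if other_gap_policy == "ignore":
        denom = sum(1 for r in residues if r != GAP_CHAR)
    else:
        denom = len(residues)
    counts: dict[str, int] = {}
    for r in residues:
        if r != GAP_CHAR and r != "X":  # X never counts as conserved
            counts[r] = counts.get(r, 0) + 1
    if not counts or denom == 0:
        return (None, 0.0)
    best = min(counts, key=lambda aa: (-counts[aa], _AA_ORDER[aa]))
    return (best, counts[best] / denom)


def reference_unique_positions(
    alignment: Alignment, ref_id: str, other_gap_policy: str = "mismatch"
) -> list[CandidateSite]:
    """Columns where the reference carries a residue no other sequence has.

    The reference must be ungapped (and not X) at a reported column.  With
    the "mismatch" policy a gap in another sequence counts as different;
    with "ignore", gapped rows are dropped and a column where every other
    row is gapped is not reported (no evidence of uniqueness).
    """
    if len(alignment.sequences) < 2:
        raise DataError("uniqueness scan needs at least 2 sequences")
    ref = alignment.sequence(ref_id)
    cmap = alignment.coordinate_map(ref_id)
    others = [s for s in alignment.sequences if s.id != ref_id]
    sites = []
    for col in range(1, alignment.n_columns + 1):
        ref_res = ref.residues[col - 1]
        if ref_res == GAP_CHAR or ref_res == "X":
            continue
        other_res = [s.residues[col - 1] for s in others]
        if other_gap_policy == "ignore":
            other_res = [r for r in other_res if r != GAP_CHAR]
            if not other_res:
                continue
        if all(r != ref_res for r in other_res):
            sites.append(
                CandidateSite(
                    column=col,
                    reference_position=cmap.column_to_position(col),
                    reference_residue=ref_res,
                    passes=["reference-unique"],
                )
            )
    return sites


def discriminating_positions(alignment: Alignment, params: ScanParams) -> list[CandidateSite]:
    """Columns conserved in the target clade (consensus frequency at or
    above the threshold) whose target consensus differs from every
    contrast clade's consensus.

    reference_position is not filled here (no reference concept); use
    candidate_screen for reference-anchored reporting.
    """
    for clade in [params.target_clade, *params.contrast_clades]:
        _clade_members(alignment, clade)  # raises on missing clade
    sites = []
    for col in range(1, alignment.n_columns + 1):
        target_res, target_freq = clade_consensus(
            alignment, params.target_clade, col, params.other_gap_policy
        )
        if target_res is None or target_freq < params.conservation_threshold:
            continue
        consensus = {params.target_clade: (target_res, target_freq)}
        ok = True
        for clade in params.contrast_clades:
            res, freq = clade_consensus(alignment, clade, col, params.other_gap_policy)
            consensus[clade] = (res, freq)
            if params.strict_contrast:
                members = _clade_members(alignment, clade)
                present = {
                    alignment.sequence(m).residues[col - 1] for m in members
                } - {GAP_CHAR}
                if target_res in present:
                    ok = False
            else:
                if res == target_res:
                    ok = False
        if ok:
            sites.append(
                CandidateSite(
                    column=col,
                    reference_position=0,
                    reference_residue="",
                    clade_consensus=consensus,
                    passes=["clade-discriminating"],
                )
            )
    return sites


def candidate_screen(alignment: Alignment, ref_id: str, params: ScanParams) -> list[CandidateSite]:
    """Intersection of the reference-unique and clade-discriminating
    filters, reported at reference positions in ascending column order."""
    unique = {
        s.column: s
        for s in reference_unique_positions(alignment, ref_id, params.other_gap_policy)
    }
    discr = discriminating_positions(alignment, params)
    out = []
    for site in discr:
        if site.column in unique:
            u = unique[site.column]
            out.append(
                CandidateSite(
                    column=site.column,
                    reference_position=u.reference_position,
                    reference_residue=u.reference_residue,
                    clade_consensus=site.clade_consensus,
                    passes=["reference-unique", "clade-discriminating"],
                )
            )
    return sorted(out, key=lambda s: s.column)


def known_site_conservation(
    alignment: Alignment, ref_id: str, positions: list[int]
) -> list[KnownSiteReport]:
    """Per-clade conservation of user-supplied reference positions (for
    example, residues known from other organisms to bind an inhibitor).

    `conserved_in_all` is true only when every sequence carries the
    reference residue at the column (a gap anywhere breaks it).
    """
    cmap = alignment.coordinate_map(ref_id)
    ref = alignment.sequence(ref_id)
    reports = []
    for pos in positions:
        col = cmap.position_to_column(pos)  # raises if out of range
        ref_res = ref.residues[col - 1]
        consensus = {
            clade: clade_consensus(alignment, clade, col)
            for clade in sorted(set(alignment.clade_map.values()))
        }
        conserved = all(s.residues[col - 1] == ref_res for s in alignment.sequences)
        reports.append(
            KnownSiteReport(
                reference_position=pos,
                column=col,
                reference_residue=ref_res,
                clade_consensus=consensus,
                conserved_in_all=conserved,
            )
        )
    return reports


def aliphatic_index(sequence, weighted: bool = True) -> float:
    """Aliphatic index of an ungapped protein sequence.

    weighted=True gives the classical Ikai form
        Ai = 100 * (X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu))
    on mole fractions X; weighted=False gives the plain percentage of
    Ala+Val+Ile+Leu residues.
    """
    residues = sequence.ungapped() if hasattr(sequence, "ungapped") else str(sequence).replace(GAP_CHAR, "")
    if not residues:
        raise DataError("aliphatic index of an empty sequence is undefined")
    n = len(residues)
    xa = residues.count("A") / n
    xv = residues.count("V") / n
    xi = residues.count("I") / n
    xl = residues.count("L") / n
    if weighted:
        return 100.0 * (xa + 2.9 * xv + 3.9 * (xi + xl))
    return 100.0 * (xa + xv + xi + xl)


def sites_to_tsv(sites: list[CandidateSite]) -> str:
    """TSV report: column, reference position/residue, per-clade
    consensus (residue:frequency), filters passed."""
    clades = sorted({c for s in sites for c in s.clade_consensus})
    header = ["column", "ref_position", "ref_residue"] + [
        f"consensus_{c}" for c in clades
    ] + ["passes"]
    lines = ["\t".join(header)]
    for s in sites:
        row = [str(s.column), str(s.reference_position), s.reference_residue]
        for c in clades:
            res, freq = s.clade_consensus.get(c, (None, 0.0))
            row.append(f"{res or '.'}:{freq:.3f}")
        row.append(",".join(s.passes))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
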