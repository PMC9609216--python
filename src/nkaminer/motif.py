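"""Assembly-motif scanning, reference-coordinate site mapping, similarity.

The Ser-Tyr-Gly-Gln/Glu (SYGQ) tetrapeptide is required for assembly of
the Na,K-ATPase alpha and beta subunits.  A width-4 window counts as a hit
when it matches SYGQ or SYGE exactly, or differs at exactly one position
by a substitution with positive BLOSUM62 score ("similar" mismatch).

Residue positions are reported in the 1-based coordinate system of a
reference protein (the published analysis used GenBank ADB19852.1, Sus
scrofa); query sequences are placed onto that system by global alignment,
so e.g. the dipeptide starting at reference position 208 can be read off
any query regardless of indels elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .config import DEFAULT_SITES, SiteDef
from .io import ProteinRecord

MOTIF_TEMPLATES = ("SYGQ", "SYGE")

GAP_OPEN = 10.0
GAP_EXTEND = 1.0

# Ambiguity letters absent from BLOSUM62 score via documented stand-ins.
_FALLBACK = {"U": "C", "O": "K", "J": "X"}


def _build_score_matrix() -> np.ndarray:
    """26x26 BLOSUM62 lookup indexed by letter ordinal (A=0..Z=25)."""
    blosum = substitution_matrices.load("BLOSUM62")
    letters = set(blosum.alphabet)
    mat = np.zeros((26, 26))
    for i in range(26):
        a = chr(ord("A") + i)
        a = a if a in letters else _FALLBACK.get(a, "X")
        for j in range(26):
            b = chr(ord("A") + j)
            b = b if b in letters else _FALLBACK.get(b, "X")
            mat[i, j] = blosum[a][b]
    return mat


BLOSUM62 = _build_score_matrix()


def blosum_score(a: str, b: str) -> float:
    return float(BLOSUM62[ord(a) - 65, ord(b) - 65])


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64) - 65


# ---------------------------------------------------------------------------
# Motif scanning


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    position: int  # 1-based start in the query
    matched: str
    template: str
    mismatches: int
    mismatch_detail: Optional[tuple[int, str, str, float]] = None
    # (position in template 1-4, template residue, observed residue, score)


def _window_hit(window: str, sequence_id: str, position: int) -> Optional[MotifHit]:
    best: Optional[MotifHit] = None
    for template in MOTIF_TEMPLATES:
        diffs = [k for k in range(4) if window[k] != template[k]]
        if not diffs:
            return MotifHit(sequence_id, position, window, template, 0)
        if len(diffs) == 1:
            k = diffs[0]
            s = blosum_score(window[k], template[k])
            if s > 0 and best is None:
                best = MotifHit(
                    sequence_id, position, window, template, 1,
                    (k + 1, template[k], window[k], s),
                )
    return best


def scan_assembly_motif(sequence: str, sequence_id: str = "") -> list[MotifHit]:
    """All width-4 windows matching SYGQ/SYGE exactly or with one similar
    mismatch; one best hit per window (exact beats 1-mismatch, SYGQ beats
    SYGE on ties)."""
    hits = []
    for i in range(len(sequence) - 3):
        hit = _window_hit(sequence[i : i + 4], sequence_id, i + 1)
        if hit is not None:
            hits.append(hit)
    return hits


def _round2(numerator: int, denominator: int) -> float:
    """Exact rational x 100 rounded half-up to 2 decimals."""
    q = Decimal(numerator * 100) / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def motif_prevalence(
    records: Sequence[ProteinRecord], grouping: str = "group"
) -> dict[str, Optional[float]]:
    """Percent of sequences per group carrying >= 1 motif hit (2 decimals)."""
    tally: dict[str, list[int]] = {}
    for rec in records:
        label = getattr(rec, grouping)
        if label is None:
            raise ValueError(f"{rec.id}: missing {grouping} label")
        carrier = int(bool(scan_assembly_motif(rec.sequence, rec.id)))
        tally.setdefault(label, [0, 0])
        tally[label][0] += carrier
        tally[label][1] += 1
    return {
        g: (_round2(c, n) if n else None) for g, (c, n) in sorted(tally.items())
    }


# ---------------------------------------------------------------------------
# Global alignment and site mapping


@dataclass
class AlignmentResult:
    query_aligned: str
    reference_aligned: str
    score: float
    #: 1-based reference position -> 1-based query position, or 0 for a gap.
    column_map: np.ndarray

    def query_position(self, reference_position: int) -> int:
        return int(self.column_map[reference_position - 1])


def global_align(query: str, reference: str,
                 gap_open: float = GAP_OPEN, gap_extend: float = GAP_EXTEND,
                 score_matrix: np.ndarray | None = None) -> AlignmentResult:
    """Needleman-Wunsch global alignment (BLOSUM62, affine gaps).

    Deterministic traceback: diagonal > up > left on ties.
    """
    from ._nw import align_codes

    if not query or not reference:
        raise ValueError("both sequences must be non-empty")
    mat = BLOSUM62 if score_matrix is None else score_matrix
    score, moves = align_codes(_encode(query), _encode(reference), mat,
                               gap_open, gap_extend)
    qa, ra = [], []
    i = j = 0
    colmap = np.zeros(len(reference), dtype=np.int64)
    for mv in moves:
        if mv == 0:
            qa.append(query[i]); ra.append(reference[j])
            colmap[j] = i + 1
            i += 1; j += 1
        elif mv == 1:
            qa.append(query[i]); ra.append("-")
            i += 1
        else:
            qa.append("-"); ra.append(reference[j])
            j += 1
    return AlignmentResult("".join(qa), "".join(ra), score, colmap)


def map_site(alignment: AlignmentResult, reference_position: int, width: int = 2) -> str:
    """Query residues aligned to reference columns [pos, pos+width-1].

    Any gap among those columns yields the state ``"gap"``.
    """
    n_ref = len(alignment.column_map)
    if not 1 <= reference_position <= n_ref - width + 1:
        raise ValueError(
            f"reference position {reference_position} out of range 1..{n_ref - width + 1}"
        )
    out = []
    for k in range(width):
        qpos = alignment.column_map[reference_position - 1 + k]
        if qpos == 0:
            return "gap"
        out.append(qpos)
    query = alignment.query_aligned.replace("-", "")
    return "".join(query[p - 1] for p in out)


@dataclass
class SiteReport:
    sites: tuple[SiteDef, ...]
    per_sequence: pd.DataFrame  # index id; columns: group, isoform, site_<pos>
    group_percent: dict[int, pd.DataFrame]    # site pos -> group x state %
    isoform_percent: dict[int, pd.DataFrame]  # site pos -> isoform x state %


def _percent_table(states: pd.Series, labels: pd.Series) -> pd.DataFrame:
    mask = labels != ""
    ct = pd.crosstab(labels[mask], states[mask])
    return (100.0 * ct.div(ct.sum(axis=1), axis=0)).sort_index()


def site_state_table(
    records: Sequence[ProteinRecord], reference: ProteinRecord,
    sites: Iterable[SiteDef] = DEFAULT_SITES,
) -> SiteReport:
    """Observed dipeptide state at each reference site for every sequence,
    with per-group and per-isoform percentage summaries."""
    sites = tuple(sites)
    rows = {}
    for rec in records:
        aln = global_align(rec.sequence, reference.sequence)
        row = {"group": rec.group or "", "isoform": rec.isoform or ""}
        for site in sites:
            row[f"site_{site.position}"] = map_site(aln, site.position)
        rows[rec.id] = row
    per_seq = pd.DataFrame.from_dict(rows, orient="index")
    group_pct, isoform_pct = {}, {}
    for site in sites:
        col = per_seq[f"site_{site.position}"]
        group_pct[site.position] = _percent_table(col, per_seq["group"])
        isoform_pct[site.position] = _percent_table(col, per_seq["isoform"])
    return SiteReport(sites, per_seq, group_pct, isoform_pct)


# ---------------------------------------------------------------------------
# Similarity


def percent_identity(a: str, b: str) -> float:
    """Identical aligned residue pairs / gap-free columns x 100."""
    aln = global_align(a, b)
    same = cols = 0
    for x, y in zip(aln.query_aligned, aln.reference_aligned):
        if x != "-" and y != "-":
            cols += 1
            same += x == y
    return 100.0 * same / cols if cols else 0.0


def group_similarity(
    records: Sequence[ProteinRecord], grouping: str = "group"
) -> pd.DataFrame:
    """Mean pairwise percent identity within (diagonal) and between groups.

    Singleton groups have no within-group pairs; their diagonal is NaN.
    """
    labels = sorted({getattr(r, grouping) for r in records if getattr(r, grouping)})
    by = {g: [r for r in records if getattr(r, grouping) == g] for g in labels}
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for gi in labels:
        for gj in labels:
            if gj < gi:
                continue
            if gi == gj:
                members = by[gi]
                vals = [
                    percent_identity(members[i].sequence, members[j].sequence)
                    for i in range(len(members))
                    for j in range(i + 1, len(members))
                ]
            else:
                vals = [
                    percent_identity(a.sequence, b.sequence)
                    for a in by[gi] for b in by[gj]
                ]
            if vals:
                out.loc[gi, gj] = out.loc[gj, gi] = float(np.mean(vals))
    return out
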