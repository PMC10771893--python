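"""Percent identity: global alignment, identity matrices, lineage markers.

Identity here uses the both-ungapped denominator: a column counts only when
neither sequence has a gap there, and matches are exact residue equality.
That convention is symmetric in the two sequences and stable under region
restriction; the :class:`IdentityMatrix` carries a ``convention`` tag so
alternatives could be added unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedIdentityError
from .records import ALIGNMENT_COLUMN, GAP, Msa, Region, SeqRecord

BOTH_UNGAPPED = "both_ungapped"


# ---------------------------------------------------------------------------
# Needleman–Wunsch global alignment (linear gap penalty)
# ---------------------------------------------------------------------------

def global_align(
    a: SeqRecord,
    b: SeqRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> tuple[SeqRecord, SeqRecord, float]:
    """Optimal global alignment of two ungapped sequences.

    Ties in the traceback are broken deterministically: diagonal
    (match/mismatch) over up (gap in b) over left (gap in a). An empty input
    aligns against all gaps with score gap * len(other). Returns the two
    gapped records and the optimal score.
    """
    sa, sb = a.residues, b.residues
    if GAP in sa or GAP in sb:
        raise ValueError("global_align expects ungapped inputs")
    n, m = len(sa), len(sb)
    F = np.empty((n + 1, m + 1))
    F[0, :] = gap * np.arange(m + 1)
    F[:, 0] = gap * np.arange(n + 1)
    eq = (
        np.frombuffer(sa.encode(), dtype=np.uint8)[:, None]
        == np.frombuffer(sb.encode(), dtype=np.uint8)[None, :]
    )
    sub = np.where(eq, match, mismatch)
    for i in range(1, n + 1):
        diag = F[i - 1, :-1] + sub[i - 1]
        up = F[i - 1, 1:] + gap
        row = F[i]
        prev = row[0]
        for j in range(1, m + 1):
            prev = max(diag[j - 1], up[j - 1], prev + gap)
            row[j] = prev
    # traceback, diagonal > up > left on ties
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + gap:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            j -= 1
    rec_a = SeqRecord(id=a.id, residues="".join(reversed(out_a)))
    rec_b = SeqRecord(id=b.id, residues="".join(reversed(out_b)))
    return rec_a, rec_b, float(F[n, m])


# ---------------------------------------------------------------------------
# Percent identity
# ---------------------------------------------------------------------------

def percent_identity(
    a: str | SeqRecord,
    b: str | SeqRecord,
    region: Region | None = None,
) -> float:
    """100 * matches / both-ungapped columns over equal-length gapped
    sequences, optionally restricted to an alignment-column region.

    Raises UndefinedIdentityError when no column has both residues present.
    The value is returned at full precision; reports round to 1 decimal.
    """
    sa = a.residues if isinstance(a, SeqRecord) else a
    sb = b.residues if isinstance(b, SeqRecord) else b
    if len(sa) != len(sb):
        raise ValueError(f"gapped lengths differ: {len(sa)} vs {len(sb)}")
    if region is not None:
        if region.space != ALIGNMENT_COLUMN:
            raise ValueError("region must be in alignment-column space")
        if region.end > len(sa):
            raise ValueError("region exceeds alignment width")
        sa, sb = sa[region.start : region.end], sb[region.start : region.end]
    both = [(x, y) for x, y in zip(sa, sb) if x != GAP and y != GAP]
    if not both:
        raise UndefinedIdentityError("no mutually ungapped columns")
    matches = sum(x == y for x, y in both)
    return 100.0 * matches / len(both)


@dataclass
class IdentityMatrix:
    """Symmetric per-pair percent identity over the species of an Msa."""

    ids: list[str]
    values: np.ndarray
    region: Region | None = None
    convention: str = BOTH_UNGAPPED
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("identity values must be finite")
        self._index = {s: i for i, s in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        return pd.DataFrame(
            np.round(self.values, decimals), index=self.ids, columns=self.ids
        )


def identity_matrix(msa: Msa, region: Region | None = None) -> IdentityMatrix:
    """All-pairs percent identity on the supplied alignment's columns."""
    n = len(msa.ids)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(msa.records[i], msa.records[j], region)
            values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids=list(msa.ids), values=values, region=region)


def write_identity_tables(
    whole: IdentityMatrix,
    domain: IdentityMatrix,
    path,
    decimals: int = 1,
) -> None:
    """TSV with whole-sequence identities in the lower-left triangle and
    domain-only identities in the upper-right, blank diagonal — the layout of
    a two-in-one pairwise comparison table."""
    if whole.ids != domain.ids:
        raise ValueError("matrices cover different species")
    ids = whole.ids
    rows = []
    for i, a in enumerate(ids):
        row = []
        for j in range(len(ids)):
            if i == j:
                row.append("")
            elif i > j:
                row.append(f"{whole.values[i, j]:.{decimals}f}")
            else:
                row.append(f"{domain.values[i, j]:.{decimals}f}")
        rows.append(row)
    pd.DataFrame(rows, index=ids, columns=ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Lineage-specific residues
# ---------------------------------------------------------------------------

def find_lineage_specific_residues(
    msa: Msa,
    target: str,
    background: set[str] | list[str],
) -> list[tuple[int, str, str]]:
    """Columns where the target carries a residue different from a residue
    shared by every background species (all non-gap; background unanimous).

    Returns (alignment column 0-based, target residue, background residue)
    tuples; human-readable reports print columns 1-based.
    """
    background = list(background)
    if not background:
        raise ValueError("background must be nonempty")
    tgt = msa[target].residues
    bg = [msa[b].residues for b in background]
    hits = []
    for col in range(msa.n_cols):
        t = tgt[col]
        states = {s[col] for s in bg}
        if t == GAP or GAP in states or len(states) != 1:
            continue
        (b,) = states
        if t != b:
            hits.append((col, t, b))
    return hits


def format_lineage_report(hits: list[tuple[int, str, str]], target: str) -> str:
    lines = [f"# {len(hits)} {target}-specific residue(s); positions are 1-based"]
    for col, t, b in hits:
        lines.append(f"position {col + 1}: {target}={t}, background={b}")
    return "\n".join(lines)
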