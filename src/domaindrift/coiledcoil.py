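"""Coiled-coil domain calling by windowed heptad-propensity scoring.

A coiled coil is a run of heptad repeats (positions labelled a-g) whose a and
d positions are hydrophobic. The scorer slides a window (default 28 residues,
four heptads) over the protein at each of the 7 possible register phases and
sums per-(residue, heptad-position) log-odds from a propensity table. A
residue's score is the best score of any window covering it; maximal runs of
residues at or above the table's threshold become calls, with runs separated
by fewer than 7 residues merged (a single broken heptad should not split a
domain).

The shipped table is synthetic — authored for this package rather than
trained on a coiled-coil database — so all downstream analyses also accept
user-supplied domain coordinates; the predictor is a fallback, not the
ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .records import ALIGNMENT_COLUMN, GAP, Msa, Region, SeqRecord

HEPTAD = "abcdefg"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PropensityTable:
    """Log-odds score for each (amino acid, heptad position) pair."""

    scores: dict[str, np.ndarray]  # aa -> 7 values for positions a..g
    window: int = 28
    threshold: float = 18.0

    def __post_init__(self):
        if set(self.scores) != set(AMINO_ACIDS):
            missing = set(AMINO_ACIDS) - set(self.scores)
            raise ValueError(f"table must cover all 20 amino acids (missing {sorted(missing)})")
        for aa, row in self.scores.items():
            row = np.asarray(row, dtype=float)
            if row.shape != (7,) or not np.all(np.isfinite(row)):
                raise ValueError(f"bad score row for {aa!r}")
            self.scores[aa] = row
        if self.window % 7 != 0 or self.window <= 0:
            raise ValueError("window must be a positive multiple of 7")
        # unknown residues (X, *) score at the table minimum: conservative,
        # discourages calls through uncertain sequence
        self.unknown_score = min(float(r.min()) for r in self.scores.values())

    def score(self, residue: str, heptad_pos: int) -> float:
        row = self.scores.get(residue)
        if row is None:
            return self.unknown_score
        return float(row[heptad_pos % 7])


def load_propensity_table(path: str | os.PathLike | None = None) -> PropensityTable:
    """Read a table TSV (20 rows x 7 columns plus '# window' / '# threshold'
    metadata lines). With no path, loads the packaged synthetic table."""
    if path is None:
        ref = resources.files("domaindrift.data") / "heptad_propensities_synthetic.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    window, threshold = 28, 18.0
    scores: dict[str, np.ndarray] = {}
    header_seen = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("# ").split("\t")
            if len(parts) == 2 and parts[0] == "window":
                window = int(parts[1])
            elif len(parts) == 2 and parts[0] == "threshold":
                threshold = float(parts[1])
            continue
        fields = line.split("\t")
        if not header_seen:
            header_seen = True  # column header row
            continue
        scores[fields[0]] = np.array([float(x) for x in fields[1:8]])
    return PropensityTable(scores=scores, window=window, threshold=threshold)


# ---------------------------------------------------------------------------
# Scoring and calling
# ---------------------------------------------------------------------------

def window_score(
    seq: SeqRecord | str,
    start: int,
    phase: int,
    table: PropensityTable,
) -> float:
    """Sum of positional log-odds over table.window residues starting at
    ``start``; residue at offset k occupies heptad position (k + phase) % 7."""
    residues = seq.residues if isinstance(seq, SeqRecord) else seq
    if GAP in residues:
        raise ValueError("window_score expects an ungapped sequence")
    if start < 0 or start + table.window > len(residues):
        raise ValueError("window does not fit in the sequence")
    return sum(
        table.score(residues[start + k], (k + phase) % 7) for k in range(table.window)
    )


@dataclass
class CoiledCoilCall:
    region: Region  # sequence space
    phase: int  # register phase of the best-scoring window in the call
    max_score: float
    score_track: np.ndarray  # per-residue best covering-window score


def _score_tracks(residues: str, table: PropensityTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue best score over all covering windows and phases, plus the
    phase of each residue's best window."""
    L, w = len(residues), table.window
    aa_scores = np.array(
        [
            [table.score(res, p) for p in range(7)]
            for res in residues
        ]
    )  # (L, 7)
    best = np.full(L, -np.inf)
    best_phase = np.zeros(L, dtype=int)
    for phase in range(7):
        # score of window starting at s under this start-phase
        pos = (np.arange(L) + phase) % 7
        per_res = aa_scores[np.arange(L), pos]
        csum = np.concatenate([[0.0], np.cumsum(per_res)])
        win = csum[w:] - csum[:-w]  # (L - w + 1,)
        # residue i is covered by windows starting in [i-w+1, i]
        for s, ws in enumerate(win):
            lo, hi = s, s + w
            seg = best[lo:hi]
            upd = ws > seg
            seg[upd] = ws
            best_phase[lo:hi][upd] = phase
    return best, best_phase


def predict_coiled_coil(
    seq: SeqRecord,
    table: PropensityTable | None = None,
) -> list[CoiledCoilCall]:
    """Call coiled-coil regions: maximal runs of residues whose best covering
    window scores >= the table threshold, merged when separated by < 7
    residues. A sequence shorter than the window yields no calls."""
    if table is None:
        table = load_propensity_table()
    residues = seq.residues
    if GAP in residues:
        raise ValueError("predict_coiled_coil expects an ungapped sequence")
    if len(residues) < table.window:
        return []
    best, best_phase = _score_tracks(residues, table)
    above = best >= table.threshold
    # maximal runs
    runs: list[list[int]] = []
    i = 0
    L = len(residues)
    while i < L:
        if above[i]:
            j = i
            while j + 1 < L and above[j + 1]:
                j += 1
            runs.append([i, j + 1])
            i = j + 1
        else:
            i += 1
    # merge runs separated by < 7 residues
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < 7:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    calls = []
    for start, end in merged:
        peak = start + int(np.argmax(best[start:end]))
        calls.append(
            CoiledCoilCall(
                region=Region(start, end, "sequence"),
                phase=int(best_phase[peak]),
                max_score=float(best[peak]),
                score_track=best.copy(),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Mapping a reference-sequence region across an alignment
# ---------------------------------------------------------------------------

@dataclass
class MappedRegion:
    alignment_region: Region  # alignment-column space
    per_species: dict[str, Region | None]  # sequence-space; None when all-gap


def map_region_across_msa(msa: Msa, reference: str, region: Region) -> MappedRegion:
    """Convert a residue interval of the (gapped) reference into alignment
    columns, then into each species' own sequence coordinates. A species with
    only gaps inside the mapped columns gets None."""
    ref = msa[reference].residues
    ungapped_len = sum(1 for c in ref if c != GAP)
    if region.end > ungapped_len:
        raise ValueError(
            f"region [{region.start},{region.end}) exceeds reference length {ungapped_len}"
        )
    # residue index -> alignment column for the reference
    cols = [i for i, c in enumerate(ref) if c != GAP]
    col_start = cols[region.start]
    col_end = cols[region.end - 1] + 1
    aln_region = Region(col_start, col_end, ALIGNMENT_COLUMN)

    per_species: dict[str, Region | None] = {}
    for rec in msa.records:
        before = sum(1 for c in rec.residues[:col_start] if c != GAP)
        inside = sum(1 for c in rec.residues[col_start:col_end] if c != GAP)
        per_species[rec.id] = (
            Region(before, before + inside, "sequence") if inside else None
        )
    return MappedRegion(alignment_region=aln_region, per_species=per_species)


def calls_to_bed(calls: list[CoiledCoilCall], name: str) -> str:
    """BED lines (0-based half-open) for a sequence's calls."""
    return "\n".join(
        f"{name}\t{c.region.start}\t{c.region.end}\tcoiled_coil\t{c.max_score:.2f}\t+"
        for c in calls
    )
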