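"""CDS evolution under HKY85 with discrete-gamma rate heterogeneity.

The generator evolves a protein-coding nucleotide sequence along a user tree
and translates the leaves, emulating a small ortholog family: a 9-taxon
mammal panel (3 primates, 4 domesticated animals, 2 rodents) with a
contiguous coiled-coil-like domain whose substitution rate can be scaled per
edge. Default substitution parameters are the HKY+G fit used throughout the
package: base frequencies (A, C, G, T) = (0.2844, 0.2519, 0.2947, 0.1690),
Ti/Tv = 2.2233, gamma shape 0.9665, no invariable sites.

Design points worth knowing:

* ``domain_multiplier`` maps tree edges (identified by the leaf set below the
  edge, or a single leaf name for a terminal edge) to a rate factor applied to
  domain sites on that edge. Edges absent from the map use
  ``domain_background_rate`` — below 1 this models purifying selection on the
  functional domain, the background state of a conserved motif.
* Site rates (gamma category, invariable flag) are drawn once at the root and
  shared across the tree (rates-across-sites).
* Codons that would become stops — at the root draw or after evolving an
  edge — are redrawn until stop-free, which is rejection sampling from the
  stop-conditioned codon law; :func:`expected_pairwise_stats` reproduces that
  law exactly for calibration.
* One master seed; per-edge streams are derived by hashing the edge's leaf
  set, so traversal order cannot change the output.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio.Seq import Seq
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

from .errors import DomainDriftError
from .records import CODON, Msa, Region, SeqRecord
from .tree import PhyloTree, read_newick

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T

DEFAULT_BASE_FREQS = (0.2844, 0.2519, 0.2947, 0.1690)
DEFAULT_TI_TV = 2.2233
DEFAULT_GAMMA_SHAPE = 0.9665

_STOP_CODONS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    tree: PhyloTree
    n_codons: int
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    ti_tv: float = DEFAULT_TI_TV
    gamma_shape: float = DEFAULT_GAMMA_SHAPE
    p_invariable: float = 0.0
    n_gamma_categories: int = 4
    domain_region: Region | None = None
    domain_multiplier: Mapping = field(default_factory=dict)
    domain_background_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.tree, str):
            self.tree = read_newick(self.tree)
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs <= 0):
            raise ValueError("base_freqs must be 4 positive numbers")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"base_freqs sum to {freqs.sum()}, not 1")
        if self.ti_tv <= 0:
            raise ValueError("ti_tv must be positive")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if not (0 <= self.p_invariable < 1):
            raise ValueError("p_invariable must be in [0, 1)")
        if self.n_gamma_categories < 1:
            raise ValueError("need at least one gamma category")
        if self.n_codons < 1:
            raise ValueError("n_codons must be positive")
        if self.domain_region is not None:
            if self.domain_region.space != CODON:
                raise ValueError("domain_region must be in codon space")
            if self.domain_region.end > self.n_codons:
                raise ValueError("domain_region exceeds n_codons")
        if self.domain_background_rate <= 0:
            raise ValueError("domain_background_rate must be positive")
        norm: dict[frozenset, float] = {}
        for key, factor in dict(self.domain_multiplier).items():
            if factor <= 0:
                raise ValueError(f"domain multiplier for {key!r} must be positive")
            fs = frozenset([key]) if isinstance(key, str) else frozenset(key)
            norm[fs] = float(factor)
        self.domain_multiplier = norm

    def edge_domain_factor(self, leafset: frozenset[str]) -> float:
        return self.domain_multiplier.get(leafset, self.domain_background_rate)


# ---------------------------------------------------------------------------
# HKY85 rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def kappa_from_ti_tv(ti_tv: float, base_freqs) -> float:
    """Convert the printed Ti/Tv ratio to the HKY kappa parameter using
    Ti/Tv = kappa (pi_A pi_G + pi_C pi_T) / ((pi_A + pi_G)(pi_C + pi_T))."""
    pa, pc, pg, pt = base_freqs
    return ti_tv * (pa + pg) * (pc + pt) / (pa * pg + pc * pt)


def hky_rate_matrix(config: SimulationConfig) -> np.ndarray:
    """HKY85 instantaneous rate matrix, scaled to one expected substitution
    per unit branch length at stationarity (sum_i pi_i * -q_ii = 1)."""
    pi = np.asarray(config.base_freqs, dtype=float)
    kappa = kappa_from_ti_tv(config.ti_tv, pi)
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = kappa * pi[j] if (i, j) in _TRANSITIONS else pi[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1."""
    if t < 0:
        raise ValueError("branch length must be nonnegative")
    return expm(np.asarray(Q, dtype=float) * t)


class _Propagator:
    """Spectral form of a reversible Q for fast P(t) at many t values."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        S = Q * d[:, None] / d[None, :]  # D^{1/2} Q D^{-1/2}, symmetric for reversible Q
        B = (S + S.T) / 2.0  # averaging kills round-off asymmetry
        self._eval, self._evec = np.linalg.eigh(B)
        self._left = self._evec / d[:, None]
        self._right = (self._evec * d[:, None]).T

    def P(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._eval * t)) @ self._right
        np.clip(P, 0.0, 1.0, out=P)
        return P / P.sum(axis=1, keepdims=True)


def discrete_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Equal-probability discrete gamma rates (category medians), normalized
    to mean exactly 1."""
    q = (np.arange(n_categories) + 0.5) / n_categories
    rates = gamma_dist.ppf(q, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

def translate(cds: SeqRecord) -> SeqRecord:
    """Translate an ungapped CDS with the standard genetic code; stop -> '*'."""
    seq = cds.residues
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3 ({cds.id})")
    bad = set(seq) - set(NT)
    if bad:
        raise ValueError(f"ambiguous or non-nucleotide characters {sorted(bad)} in {cds.id}")
    protein = str(Seq(seq).translate())
    return SeqRecord(id=cds.id, residues=protein, description=cds.description)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    nucleotide: Msa
    protein: Msa
    site_rates: np.ndarray        # per nucleotide site, gamma rate (0 if invariable)
    site_categories: np.ndarray   # per nucleotide site, category index (-1 invariable)
    in_domain: np.ndarray         # per nucleotide site, bool

    def site_table(self) -> "pd.DataFrame":  # noqa: F821 - imported lazily
        import pandas as pd

        return pd.DataFrame(
            {
                "site": np.arange(self.site_rates.size),
                "codon": np.arange(self.site_rates.size) // 3,
                "gamma_category": self.site_categories,
                "rate": self.site_rates,
                "in_domain": self.in_domain.astype(int),
            }
        )


def _edge_rng(seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), zlib.crc32(tag.encode())))
    )


def _sample_rows(P: np.ndarray, parents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parents.size)
    return (u[:, None] > cum[parents]).sum(axis=1)


def _find_stops(seq_idx: np.ndarray) -> np.ndarray:
    codons = seq_idx.reshape(-1, 3)
    t, a, g = NT_INDEX["T"], NT_INDEX["A"], NT_INDEX["G"]
    is_stop = (codons[:, 0] == t) & (
        ((codons[:, 1] == a) & ((codons[:, 2] == a) | (codons[:, 2] == g)))
        | ((codons[:, 1] == g) & (codons[:, 2] == a))
    )
    return np.nonzero(is_stop)[0]


def _draw_root(n_codons: int, pi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    seq = _sample_rows(np.tile(pi, (1, 1)), np.zeros(3 * n_codons, dtype=int), rng)
    for _ in range(10_000):
        stops = _find_stops(seq)
        if stops.size == 0:
            return seq
        redraw = _sample_rows(np.tile(pi, (1, 1)), np.zeros(3 * stops.size, dtype=int), rng)
        sites = (stops[:, None] * 3 + np.arange(3)).ravel()
        seq[sites] = redraw
    raise DomainDriftError("root draw failed to clear stop codons")


def _evolve_edge(
    parent: np.ndarray,
    t: float,
    site_factor: np.ndarray,
    prop: _Propagator,
    rng: np.random.Generator,
) -> np.ndarray:
    child = parent.copy()
    factors = np.unique(site_factor)
    P_cache: dict[float, np.ndarray] = {}
    for f in factors:
        mask = site_factor == f
        if t * f == 0.0:
            continue
        P = prop.P(t * f)
        P_cache[f] = P
        child[mask] = _sample_rows(P, parent[mask], rng)
    # reject codons that became stops: redraw the whole codon from the parent
    for _ in range(10_000):
        stops = _find_stops(child)
        if stops.size == 0:
            return child
        sites = (stops[:, None] * 3 + np.arange(3)).ravel()
        for f, P in P_cache.items():
            mask = site_factor[sites] == f
            if mask.any():
                child[sites[mask]] = _sample_rows(P, parent[sites[mask]], rng)
        if not P_cache:  # zero-length edge cannot create stops, but be safe
            return child
    raise DomainDriftError("edge evolution failed to clear stop codons")


def simulate_cds(config: SimulationConfig) -> SimulationResult:
    """Simulate a stop-free CDS alignment (gap-free Msa) and its translation.

    Deterministic under a fixed seed; a different seed gives different site
    patterns.
    """
    tree = config.tree
    if len(tree.leaf_names) < 2:
        raise ValueError("tree must have at least 2 leaves")
    pi = np.asarray(config.base_freqs, dtype=float)
    Q = hky_rate_matrix(config)
    prop = _Propagator(Q, pi)

    n_sites = 3 * config.n_codons
    root_rng = _edge_rng(config.seed, "__root__")

    # per-site rates, drawn once, shared across the tree
    cats = root_rng.integers(0, config.n_gamma_categories, size=n_sites)
    rates = discrete_gamma_rates(config.gamma_shape, config.n_gamma_categories)[cats]
    if config.p_invariable > 0:
        invar = root_rng.random(n_sites) < config.p_invariable
        cats = np.where(invar, -1, cats)
        rates = np.where(invar, 0.0, rates / (1.0 - config.p_invariable))

    in_domain = np.zeros(n_sites, dtype=bool)
    if config.domain_region is not None:
        in_domain[3 * config.domain_region.start : 3 * config.domain_region.end] = True

    root_seq = _draw_root(config.n_codons, pi, root_rng)

    sequences: dict[str, np.ndarray] = {}

    def recurse(node, seq):
        if node.is_leaf:
            sequences[node.name] = seq
            return
        for child in node.children:
            leafset = frozenset(child.leaf_names())
            factor = config.edge_domain_factor(leafset)
            site_factor = rates * np.where(in_domain, factor, 1.0)
            rng = _edge_rng(config.seed, ",".join(sorted(leafset)))
            child_seq = _evolve_edge(seq, child.length or 0.0, site_factor, prop, rng)
            recurse(child, child_seq)

    recurse(tree.root, root_seq)

    order = tree.leaf_names
    nt_records = [
        SeqRecord(id=name, residues="".join(NT[i] for i in sequences[name]))
        for name in order
    ]
    prot_records = [translate(rec) for rec in nt_records]
    return SimulationResult(
        nucleotide=Msa(nt_records),
        protein=Msa(prot_records),
        site_rates=rates,
        site_categories=cats,
        in_domain=in_domain,
    )


# ---------------------------------------------------------------------------
# Exact pairwise expectations (calibration oracle)
# ---------------------------------------------------------------------------

def _rate_categories(config: SimulationConfig) -> list[tuple[float, float]]:
    rates = discrete_gamma_rates(config.gamma_shape, config.n_gamma_categories)
    w = (1.0 - config.p_invariable) / config.n_gamma_categories
    cats = [(r / (1.0 - config.p_invariable) if config.p_invariable else r, w) for r in rates]
    if config.p_invariable > 0:
        cats.append((0.0, config.p_invariable))
    return cats


def expected_pairwise_stats(config: SimulationConfig) -> dict:
    """Exact moments of the generator's law for a 2-leaf tree.

    Enumerates the 61 sense codons and the per-codon rate-category triples to
    return the expected nucleotide p-distance between the two leaves and the
    exact leaf base composition, both under the stop-codon rejection the
    simulator applies. Requires a 2-leaf tree and a uniform domain factor
    (no domain, or all factors 1).
    """
    leaves = config.tree.leaves
    if len(leaves) != 2:
        raise ValueError("exact expectations are available for 2-leaf trees only")
    if config.domain_region is not None and (
        config.domain_background_rate != 1.0
        or any(f != 1.0 for f in config.domain_multiplier.values())
    ):
        raise ValueError("exact expectations assume a uniform rate factor")

    pi = np.asarray(config.base_freqs, dtype=float)
    Q = hky_rate_matrix(config)
    prop = _Propagator(Q, pi)
    t1, t2 = (leaf.length or 0.0 for leaf in leaves)

    codons = ["".join(c) for c in itertools.product(NT, repeat=3)]
    sense = [i for i, c in enumerate(codons) if c not in _STOP_CODONS]
    p0 = np.array([pi[NT_INDEX[c[0]]] * pi[NT_INDEX[c[1]]] * pi[NT_INDEX[c[2]]] for c in codons])
    p0 = p0[sense] / p0[sense].sum()

    ham = np.zeros((64, 64))
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            ham[i, j] = sum(a != b for a, b in zip(ci, cj))
    ham = ham[np.ix_(sense, sense)]
    nt_count = np.zeros((len(sense), 4))
    for row, i in enumerate(sense):
        for ch in codons[i]:
            nt_count[row, NT_INDEX[ch]] += 1

    cats = _rate_categories(config)

    def branch_T(t: float, r1: float, r2: float, r3: float) -> np.ndarray:
        T = np.kron(np.kron(prop.P(t * r1), prop.P(t * r2)), prop.P(t * r3))
        T = T[np.ix_(sense, sense)]
        return T / T.sum(axis=1, keepdims=True)

    e_mismatch = 0.0
    comp1 = np.zeros(4)
    comp2 = np.zeros(4)
    for (r1, w1), (r2, w2), (r3, w3) in itertools.product(cats, repeat=3):
        w = w1 * w2 * w3
        Ta = branch_T(t1, r1, r2, r3)
        Tb = Ta if t2 == t1 else branch_T(t2, r1, r2, r3)
        M = Ta.T @ (p0[:, None] * Tb)
        e_mismatch += w * float((M * ham).sum())
        comp1 += w * (p0 @ Ta) @ nt_count
        comp2 += w * (p0 @ Tb) @ nt_count

    return {
        "p_distance": e_mismatch / 3.0,
        "leaf_base_freqs": (comp1 / 3.0, comp2 / 3.0),
        "root_base_freqs": (p0 @ nt_count) / 3.0,
    }


# ---------------------------------------------------------------------------
# The 9-taxon mammal preset
# ---------------------------------------------------------------------------

#: Species codes follow the common 3-letter abbreviations: Hsa human,
#: Ptr chimpanzee, Mml rhesus monkey; Cfa dog, Eca horse, Ssc pig, Bta cow;
#: Mmu mouse, Rno rat.
MAMMAL_NEWICK = (
    "(((Hsa:0.02,Ptr:0.015):0.01,Mml:0.04):0.09,"
    "((Bta:0.08,Ssc:0.08):0.03,(Cfa:0.09,Eca:0.09):0.03):0.07,"
    "(Mmu:0.035,Rno:0.035):0.3);"
)

MAMMAL_GROUPS = {
    "Hsa": "primate",
    "Ptr": "primate",
    "Mml": "primate",
    "Cfa": "domesticated",
    "Eca": "domesticated",
    "Ssc": "domesticated",
    "Bta": "domesticated",
    "Mmu": "rodent",
    "Rno": "rodent",
}

PRIMATE_TERMINALS = ("Hsa", "Ptr", "Mml")

#: 91 codons = 13 heptads, a contiguous coiled-coil-sized domain.
MAMMAL_DOMAIN = Region(140, 231, CODON)


def mammal_tree() -> PhyloTree:
    return read_newick(MAMMAL_NEWICK)


def mammal_config(
    seed: int,
    accelerate_primates: bool = False,
    n_codons: int = 300,
    domain_background_rate: float = 0.25,
    primate_multiplier: float = 3.0,
) -> SimulationConfig:
    """The study conditions: 9 mammals, a purifying-selection coiled-coil
    domain (background rate factor 0.25), optionally accelerated to 3x the
    whole-protein rate on the three primate terminal edges."""
    multiplier = (
        {name: primate_multiplier for name in PRIMATE_TERMINALS}
        if accelerate_primates
        else {}
    )
    return SimulationConfig(
        tree=mammal_tree(),
        n_codons=n_codons,
        domain_region=Region(MAMMAL_DOMAIN.start, MAMMAL_DOMAIN.end, CODON)
        if n_codons >= MAMMAL_DOMAIN.end
        else Region(0, n_codons, CODON),
        domain_multiplier=multiplier,
        domain_background_rate=domain_background_rate,
        seed=seed,
    )


def heptad_repeat_protein(
    n_heptads: int,
    phase: int = 0,
    flank: int = 0,
    seed: int = 0,
) -> tuple[SeqRecord, Region]:
    """A positive-control protein: an ideal coiled-coil heptad repeat
    (L at heptad positions a/d, E/K elsewhere) embedded between ``flank``
    scrambled residues on each side. Returns the record and the true domain
    region in sequence space."""
    rng = np.random.default_rng(seed)
    ideal = "LEKLKEE"  # positions a..g with hydrophobic a/d
    core = (ideal * (n_heptads + 2))[phase : phase + 7 * n_heptads]
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    left = "".join(rng.choice(list(alphabet), size=flank))
    right = "".join(rng.choice(list(alphabet), size=flank))
    seq = left + core + right
    return (
        SeqRecord(id="heptad_control", residues=seq),
        Region(flank, flank + 7 * n_heptads, "sequence"),
    )
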