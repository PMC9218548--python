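"""Three independent miRNA target predictors over 3'UTRs, and their consensus.

The three predictors are self-contained re-implementations in the spirit of
the canonical tool families:

* **seed matching** — canonical site classes from Watson-Crick
  complementarity to miRNA positions 2-8: ``8mer`` (match 2-8 plus an A
  opposite position 1), ``7mer-m8`` (match 2-8), ``7mer-A1`` (match 2-7 plus
  A1) and ``6mer`` (match 2-7); the most specific class wins per position.
* **duplex alignment** — a local anti-parallel miRNA:UTR alignment scored
  match +5, G:U wobble +1, mismatch -3, gap open -9 / extend -4, with
  substitution weights doubled at miRNA positions 2-8.
* **site accessibility energy** — ddG = dG(duplex) - dG(open), where
  dG(duplex) is a nearest-neighbor stacking sum over the seed-anchored
  duplex and dG(open) is the cost of forcing the site single-stranded under
  a simplified pair-stacking secondary-structure model (Nussinov-style
  minimization, minimum hairpin loop 3) on the site +- ``flank`` window.

A (miRNA, gene) pair is a *consensus target* when each method reports at
least one qualifying site in the gene's 3'UTR. Duplex and energy evaluation
are anchored at seed-complementary 6mer cores (the same pre-filter the
alignment-based tools apply); all matching reads the miRNA 5'->3' against
the UTR 5'->3' with anti-parallel complementarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

_TO_RNA = str.maketrans("acgtuT", "ACGUUU")
_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}
#: Watson-Crick plus wobble pairs
_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}

CLASS_RANK = {"none": 0, "6mer": 1, "7mer-A1": 2, "7mer-m8": 3, "8mer": 4}

# duplex alignment scoring
MATCH, WOBBLE, MISMATCH = 5.0, 1.0, -3.0
GAP_OPEN, GAP_EXTEND = 9.0, 4.0  # costs (subtracted)
SEED_POSITIONS = range(2, 9)  # miRNA positions 2..8, 1-based

# stack energies (kcal/mol): WC stacks by pair strength, any wobble -0.5
STACK_GC_GC = -3.4
STACK_GC_AU = -2.2
STACK_AU_AU = -1.0
STACK_WOBBLE = -0.5
#: intermolecular helix-initiation penalty (kcal/mol), as in standard
#: nearest-neighbor duplex thermodynamics
DUPLEX_INIT = 4.1
MIN_HAIRPIN = 3  # minimum unpaired bases in a hairpin loop


def normalize_rna(seq: str) -> str:
    """Uppercase RNA alphabet (T -> U); rejects non-nucleotide characters."""
    out = seq.translate(_TO_RNA)
    bad = set(out) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return out


def _is_pair(a: str, b: str) -> bool:
    return (a, b) in _WC or (a, b) in _WOBBLE


def _pair_kind(a: str, b: str) -> str | None:
    if (a, b) in _WOBBLE:
        return "GU"
    if (a, b) in _WC:
        return "GC" if a in "GC" else "AU"
    return None


def _stack_energy(k1: str, k2: str) -> float:
    if "GU" in (k1, k2):
        return STACK_WOBBLE
    if k1 == "GC" and k2 == "GC":
        return STACK_GC_GC
    if k1 == "AU" and k2 == "AU":
        return STACK_AU_AU
    return STACK_GC_AU


@dataclass
class TargetSite:
    """A predicted binding site; coordinates 0-based half-open on the UTR."""

    mirna: str
    gene: str
    start: int
    end: int
    core_start: int  # UTR index of the 6mer seed-complementary core
    seed_class: str
    duplex: float = float("nan")
    dg_duplex: float = float("nan")
    dg_open: float = float("nan")

    @property
    def ddg(self) -> float:
        return self.dg_duplex - self.dg_open


def find_seed_sites(mature: str, utr: str, mirna_id: str = "", gene_id: str = "") -> list[TargetSite]:
    """Scan the UTR for canonical seed-complementary sites.

    Each seed-core position is reported once, carrying its most specific
    class. The site interval spans exactly the matched bases (so an 8mer is
    8 nt, a 6mer 6 nt).
    """
    m = normalize_rna(mature)
    u = normalize_rna(utr)
    if len(m) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    core = "".join(_COMPLEMENT[c] for c in m[1:7])[::-1]  # revcomp positions 2-7
    comp_m8 = _COMPLEMENT[m[7]]
    sites: list[TargetSite] = []
    pos = u.find(core)
    while pos != -1:
        has_m8 = pos > 0 and u[pos - 1] == comp_m8
        has_a1 = pos + 6 < len(u) and u[pos + 6] == "A"
        if has_m8 and has_a1:
            cls, start, end = "8mer", pos - 1, pos + 7
        elif has_m8:
            cls, start, end = "7mer-m8", pos - 1, pos + 6
        elif has_a1:
            cls, start, end = "7mer-A1", pos, pos + 7
        else:
            cls, start, end = "6mer", pos, pos + 6
        sites.append(
            TargetSite(mirna=mirna_id, gene=gene_id, start=start, end=end,
                       core_start=pos, seed_class=cls)
        )
        pos = u.find(core, pos + 1)
    return sites


def _substitution(a: str, b: str, mirna_pos: int) -> float:
    """Score of aligning miRNA base ``a`` (1-based position) to UTR base ``b``."""
    if _pair_kind(a, b) is None:
        s = MISMATCH
    elif (a, b) in _WOBBLE:
        s = WOBBLE
    else:
        s = MATCH
    return 2.0 * s if mirna_pos in SEED_POSITIONS else s


def _gotoh_local(mature: str, window: str) -> float:
    """Best local anti-parallel alignment score of the miRNA against the
    UTR window (window is reversed internally so both run 3'->5' vs 5'->3')."""
    a = mature
    b = window[::-1]  # anti-parallel: miRNA 5' end faces window 3' end
    na, nb = len(a), len(b)
    neg = float("-inf")
    M = np.full((na + 1, nb + 1), 0.0)
    Ix = np.full((na + 1, nb + 1), neg)  # gap in window (miRNA base unpaired)
    Iy = np.full((na + 1, nb + 1), neg)
    best = 0.0
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = _substitution(a[i - 1], b[j - 1], i)
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = diag + s
            Ix[i][j] = max(M[i - 1][j] - GAP_OPEN, Ix[i - 1][j] - GAP_EXTEND)
            Iy[i][j] = max(M[i][j - 1] - GAP_OPEN, Iy[i][j - 1] - GAP_EXTEND)
            if M[i][j] > best:
                best = M[i][j]
    return float(best)


def duplex_score(mature: str, utr_window: str) -> float:
    """Local duplex alignment score; 0 for an empty window."""
    m = normalize_rna(mature)
    w = normalize_rna(utr_window)
    if len(w) == 0:
        return 0.0
    if not (len(m) - 5 <= len(w) <= len(m) + 15):
        raise ValueError("window length must be within [mature-5, mature+15]")
    return _gotoh_local(m, w)


def _anchored_pairing(mature: str, utr: str, core_start: int) -> list[str | None]:
    """Pair kind per miRNA position (1-based index k -> kind or None) when
    the seed core m2..m7 is laid onto the UTR at ``core_start``."""
    kinds: list = [None]  # index 0 unused
    for k in range(1, len(mature) + 1):
        u_idx = core_start + 7 - k
        if 0 <= u_idx < len(utr):
            kinds.append(_pair_kind(mature[k - 1], utr[u_idx]))
        else:
            kinds.append(None)
    return kinds


def duplex_free_energy(mature: str, utr: str, core_start: int) -> float:
    """Free energy of the seed-anchored duplex helix (<= 0).

    Nearest-neighbor stacking is summed over the maximal contiguous helix
    containing the seed (positions 2-7 are paired by construction of a
    core match; the helix extends outward while consecutive positions
    remain paired), plus the intermolecular helix-initiation penalty.
    Clamped at 0: a helix too weak to offset initiation contributes no
    binding energy.
    """
    m = normalize_rna(mature)
    u = normalize_rna(utr)
    kinds = _anchored_pairing(m, u, core_start)
    lo = 2
    while lo > 1 and kinds[lo - 1] is not None:
        lo -= 1
    hi = min(7, len(m))
    while hi < len(m) and kinds[hi + 1] is not None:
        hi += 1
    e = 0.0
    for k in range(lo, hi):
        if kinds[k] is not None and kinds[k + 1] is not None:
            e += _stack_energy(kinds[k], kinds[k + 1])
    if e == 0.0:
        return 0.0
    return min(0.0, e + DUPLEX_INIT)


def structure_mfe(seq: str, forbidden: frozenset | set = frozenset()) -> float:
    """Minimum free energy of the simplified stacking model.

    Structures are non-crossing sets of WC/wobble pairs with hairpin loops of
    at least :data:`MIN_HAIRPIN` unpaired bases; only stacked adjacent pairs
    carry (negative) energy, so the MFE is <= 0. Positions in ``forbidden``
    may not pair.
    """
    s = normalize_rna(seq)
    n = len(s)
    if n == 0:
        return 0.0
    forb = set(forbidden)
    pairable = np.zeros((n, n), dtype=bool)
    kind = {}
    for i in range(n):
        if i in forb:
            continue
        for j in range(i + MIN_HAIRPIN + 1, n):
            if j in forb:
                continue
            pk = _pair_kind(s[i], s[j])
            if pk is not None:
                pairable[i, j] = True
                kind[(i, j)] = pk
    V = np.zeros((n, n))
    W = np.zeros((n, n))
    for span in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            if pairable[i, j]:
                v = W[i + 1, j - 1]
                if pairable[i + 1, j - 1]:
                    v = min(
                        v,
                        V[i + 1, j - 1]
                        + _stack_energy(kind[(i, j)], kind[(i + 1, j - 1)]),
                    )
                V[i, j] = v
            w = W[i, j - 1]
            for k in range(i, j - MIN_HAIRPIN):
                if pairable[k, j]:
                    left = W[i, k - 1] if k > i else 0.0
                    cand = left + V[k, j]
                    if cand < w:
                        w = cand
            W[i, j] = w
    return float(W[0, n - 1])


def delta_delta_g(
    mature: str, utr: str, site: TargetSite, flank: int = 17
) -> tuple[float, float, float]:
    """(dG_duplex, dG_open, ddG) for one site.

    dG_open = MFE(window, site forced single-stranded) - MFE(window) >= 0,
    computed on the site +- ``flank`` window (truncated at UTR boundaries).
    """
    if flank < 0:
        raise ValueError("flank must be nonnegative")
    m = normalize_rna(mature)
    u = normalize_rna(utr)
    if not (0 <= site.start < site.end <= len(u)):
        raise ValueError("site outside UTR bounds")
    dg_duplex = duplex_free_energy(m, u, site.core_start)
    lo = max(0, site.start - flank)
    hi = min(len(u), site.end + flank)
    window = u[lo:hi]
    site_idx = frozenset(range(site.start - lo, site.end - lo))
    e_free = structure_mfe(window)
    e_open = structure_mfe(window, forbidden=site_idx)
    dg_open = e_open - e_free
    return dg_duplex, dg_open, dg_duplex - dg_open


@dataclass
class ConsensusThresholds:
    min_seed_class: str = "7mer-A1"  # least specific qualifying class
    min_duplex_score: float = 80.0
    max_ddg: float = -10.0
    flank: int = 17


@dataclass
class ConsensusResult:
    pairs: set  # {(mirna id, gene id)} passing all three methods
    per_method: dict  # method name -> set of pairs
    sites: list  # TargetSite evidence records (seed-qualified pairs)


def _duplex_window(utr: str, core_start: int, mature_len: int) -> str:
    """UTR slice covering the site plus upstream room for 3' pairing."""
    end = min(len(utr), core_start + 8)
    start = max(0, end - (mature_len + 8))
    return utr[start:end]


def evaluate_pair(
    mature: str,
    utr: str,
    thresholds: ConsensusThresholds,
    mirna_id: str = "",
    gene_id: str = "",
) -> list[TargetSite]:
    """Score every seed-anchored site of one (miRNA, UTR) pair.

    Duplex and energy metrics are evaluated only when the pair has at least
    one site of the qualifying seed class (the alignment- and energy-based
    evaluations are anchored at seed cores, so a pair with no qualifying
    seed can never reach consensus).
    """
    m = normalize_rna(mature)
    u = normalize_rna(utr)
    sites = find_seed_sites(m, u, mirna_id, gene_id)
    min_rank = CLASS_RANK[_canonical_class(thresholds.min_seed_class)]
    if not any(CLASS_RANK[s.seed_class] >= min_rank for s in sites):
        return sites
    out = []
    for s in sites:
        score = _gotoh_local(m, _duplex_window(u, s.core_start, len(m)))
        dgd, dgo, _ = delta_delta_g(m, u, s, flank=thresholds.flank)
        out.append(replace(s, duplex=score, dg_duplex=dgd, dg_open=dgo))
    return out


def _canonical_class(name: str) -> str:
    if name == "7mer":
        return "7mer-A1"
    if name not in CLASS_RANK:
        raise ValueError(f"unknown seed class {name!r}")
    return name


def consensus_targets(
    mirnas: dict,
    utrs: dict,
    thresholds: ConsensusThresholds | None = None,
) -> ConsensusResult:
    """Pairs for which all three methods report >= 1 qualifying site.

    ``mirnas`` maps miRNA id -> mature sequence; ``utrs`` maps gene id ->
    3'UTR. The consensus set is the intersection of the three per-method
    pair sets; evidence sites are retained for every seed-qualified pair.
    """
    th = thresholds or ConsensusThresholds()
    min_rank = CLASS_RANK[_canonical_class(th.min_seed_class)]
    per_method: dict = {"seed": set(), "duplex": set(), "energy": set()}
    evidence: list[TargetSite] = []
    for gid in sorted(utrs):
        utr = utrs[gid]
        for mid in sorted(mirnas):
            sites = evaluate_pair(mirnas[mid], utr, th, mid, gid)
            if not sites:
                continue
            evidence.extend(s for s in sites if not np.isnan(s.duplex))
            pair = (mid, gid)
            if any(CLASS_RANK[s.seed_class] >= min_rank for s in sites):
                per_method["seed"].add(pair)
            if any(
                not np.isnan(s.duplex) and s.duplex >= th.min_duplex_score
                for s in sites
            ):
                per_method["duplex"].add(pair)
            if any(
                not np.isnan(s.dg_duplex) and s.ddg <= th.max_ddg for s in sites
            ):
                per_method["energy"].add(pair)
    pairs = per_method["seed"] & per_method["duplex"] & per_method["energy"]
    return ConsensusResult(pairs=pairs, per_method=per_method, sites=evidence)
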