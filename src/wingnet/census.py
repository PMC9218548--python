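"""miRNA candidate acceptance filters, conservation and 5' composition.

Candidate precursor records (mature sequence, discovery score, randfold
p-value) are accepted when the discovery score exceeds 3 (strict) and the
hairpin-randomization p-value is significant. Accepted matures are called
*conserved* when they align ungapped to any reference mature over >= 18 nt
at >= 90% identity, otherwise *novel*; genuine miRNA sets typically show a
uridine preference at position 1, which :func:`five_prime_profile` reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)

#: ungapped-hit operationalization of "a reference hit"
MIN_HIT_LENGTH = 18
MIN_HIT_IDENTITY = 0.90


@dataclass(frozen=True)
class MirnaCandidate:
    precursor_id: str
    mature: str  # RNA 5'->3'
    score: float  # discovery score
    randfold_p: float
    locus: str = ""

    def __post_init__(self) -> None:
        if not 17 <= len(self.mature) <= 25:
            raise ValueError("mature length must be within [17, 25] nt")
        if not 0.0 <= self.randfold_p <= 1.0:
            raise ValueError("randfold p must lie in [0, 1]")


def filter_candidates(candidates, score_min: float = 3.0, p_max: float = 0.05):
    """Accepted candidates: score > score_min (strict) and randfold p < p_max."""
    return [c for c in candidates if c.score > score_min and c.randfold_p < p_max]


def _best_ungapped_hit(query: str, ref: str) -> bool:
    """True if some ungapped offset has a window >= 18 nt at >= 90% identity."""
    nq, nr = len(query), len(ref)
    for offset in range(-(nr - 1), nq):
        # overlap of query[i] with ref[i - offset]
        lo = max(0, offset)
        hi = min(nq, nr + offset)
        if hi - lo < MIN_HIT_LENGTH:
            continue
        matches = [query[i] == ref[i - offset] for i in range(lo, hi)]
        # best window of each admissible length on this diagonal
        for length in range(hi - lo, MIN_HIT_LENGTH - 1, -1):
            allowed = int(length * (1.0 - MIN_HIT_IDENTITY))
            run = sum(matches[:length])
            if length - run <= allowed:
                return True
            for start in range(1, (hi - lo) - length + 1):
                run += matches[start + length - 1] - matches[start - 1]
                if length - run <= allowed:
                    return True
    return False


def classify_conservation(mature: str, reference_matures) -> str:
    """"conserved" iff the mature has an ungapped >= 18 nt / >= 90% identity
    hit to any reference mature, else "novel"."""
    refs = list(reference_matures)
    if not refs:
        logger.warning("empty reference set: every mature classified novel")
        return "novel"
    for ref in refs:
        if _best_ungapped_hit(mature, ref):
            return "conserved"
    return "novel"


def five_prime_profile(matures) -> dict:
    """Nucleotide fractions at mature position 1 (sums to 1)."""
    seqs = list(matures)
    if not seqs:
        raise ValueError("empty mature set")
    counts = {n: 0 for n in "ACGU"}
    for s in seqs:
        first = s[0].upper().replace("T", "U")
        if first not in counts:
            raise ValueError(f"non-nucleotide first base {first!r}")
        counts[first] += 1
    total = len(seqs)
    return {n: c / total for n, c in counts.items()}


def collapse_redundant(candidates):
    """Optional pre-step: collapse candidates whose matures hit each other
    under the same similarity rule, keeping the highest-scoring record."""
    kept: list[MirnaCandidate] = []
    for c in sorted(candidates, key=lambda c: (-c.score, c.precursor_id)):
        if any(_best_ungapped_hit(c.mature, k.mature) for k in kept):
            continue
        kept.append(c)
    return kept


def census_summary(candidates, reference_matures) -> dict:
    accepted = filter_candidates(candidates)
    classes = {
        c.precursor_id: classify_conservation(c.mature, reference_matures)
        for c in accepted
    }
    n_cons = sum(1 for v in classes.values() if v == "conserved")
    summary = {
        "n_candidates": len(list(candidates)),
        "n_accepted": len(accepted),
        "n_conserved": n_cons,
        "n_novel": len(accepted) - n_cons,
    }
    if accepted:
        summary["five_prime_profile"] = five_prime_profile(
            [c.mature for c in accepted]
        )
    return summary
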