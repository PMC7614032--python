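"""PWM likelihood-ratio motif scanning and variant disruption scoring.

The question answered here: given a non-coding variant, which transcription-
factor binding motifs does it disrupt, and how badly?  For each PWM the
scanner finds the maximal-scoring window that spans the variant locus on the
reference sequence and again on the mutated sequence; scores are
log-likelihood ratios (natural log) of the motif model over a genome
background, normalised by the PWM's maximum attainable score so motifs of
different lengths and information content are comparable.  The disruption
score is reference-normalised score minus mutated-normalised score: positive
means binding-site loss, negative means a gained site.

Candidate matches are tiered on the reference score (Tier 1: >= 0.6,
Tier 2: [0.45, 0.6)) and reported per transcription-factor family, where a
family is the gene symbol with trailing numbers removed (NKX2-2 -> NKX2,
HIC2 -> HIC) and all FOX factors pooled.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from Bio import motifs as bio_motifs

from .genomics import Variant

__all__ = [
    "PWM",
    "MotifHit",
    "DisruptionRecord",
    "Locus",
    "AmbiguousBaseError",
    "NoSpanningWindowError",
    "read_jaspar",
    "genome_base_frequencies",
    "score_window",
    "apply_variant",
    "max_spanning_match",
    "assign_tier",
    "disruption_score",
    "family_of",
    "rank_disruptions",
    "revcomp",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
PROB_FLOOR = 1e-10  # avoids -inf while keeping mismatches strongly penalised

TIER1_MIN = 0.6
TIER2_MIN = 0.45


class AmbiguousBaseError(ValueError):
    """Window contains a non-ACGT base; its score is undefined."""


class NoSpanningWindowError(ValueError):
    """No window of the PWM's length can be placed over the variant locus."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background and score bounds.

    ``prob`` is L x 4 over A,C,G,T; ``log_odds[i, b] = ln(prob/background)``
    with probabilities floored at 1e-10 before the log.  ``max_score`` is the
    score of the per-position argmax path, an upper bound for any window.
    """

    motif_id: str
    gene_symbol: str
    prob: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        prob = np.asarray(self.prob, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if prob.ndim != 2 or prob.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: prob must be L x 4")
        if not np.allclose(prob.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.motif_id}: position probabilities must sum to 1")
        if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"{self.motif_id}: background must sum to 1")
        object.__setattr__(self, "prob", prob)
        object.__setattr__(self, "background", bg)

    @property
    def length(self) -> int:
        return self.prob.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(np.maximum(self.prob, PROB_FLOOR) / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.prob.argmax(axis=1))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int           # forward-strand offset of the window in the scanned sequence
    strand: str          # '+' or '-'
    raw_score: float     # nats
    norm_score: float    # raw_score / pwm.max_score


@dataclass(frozen=True)
class Locus:
    """Offsets a scoring window must span to count as covering the variant.

    ``offsets`` are 0-based positions in the scanned sequence.  For SNVs and
    insertions a window qualifies by touching any offset; for deletions the
    locus is the junction between the retained flanks and a window must cover
    both flanking offsets (``junction=True``).
    """

    offsets: tuple
    junction: bool = False

    def spanned_by(self, start: int, length: int) -> bool:
        end = start + length  # half-open
        if self.junction:
            return all(start <= o < end for o in self.offsets)
        return any(start <= o < end for o in self.offsets)


def read_jaspar(
    source: Union[str, Path, io.TextIOBase],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount_total: float = 0.8,
) -> list[PWM]:
    """Load JASPAR-format PFMs into probability PWMs.

    Counts in each column receive a total pseudocount of ``pseudocount_total``
    distributed proportionally to the background (MEME-style), then are
    normalised to probabilities.  PWMs with no information over the
    background (max_score <= 0) are rejected at load time, as they can never
    produce a meaningful normalised score.
    """
    bg = np.asarray(background, dtype=float)
    if not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    handle = open(source) if isinstance(source, (str, Path)) else source
    try:
        parsed = bio_motifs.parse(handle, "jaspar")
    except Exception as e:  # ragged rows, non-numeric counts
        raise ValueError(f"failed to parse JASPAR PFM input: {e}") from None
    finally:
        if isinstance(source, (str, Path)):
            handle.close()
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in BASES], dtype=float).T  # L x 4
        totals = counts.sum(axis=1, keepdims=True)
        prob = (counts + pseudocount_total * bg) / (totals + pseudocount_total)
        pwm = PWM(
            motif_id=m.matrix_id or m.name,
            gene_symbol=m.name or m.matrix_id,
            prob=prob,
            background=bg,
        )
        if pwm.max_score <= 0:
            raise ValueError(
                f"PWM {pwm.motif_id} carries no information over the background "
                "(max_score <= 0)"
            )
        out.append(pwm)
    return out


def genome_base_frequencies(seqs: Union[dict, Iterable[str]]) -> np.ndarray:
    """A,C,G,T frequencies over all sequences; ambiguity codes excluded."""
    if isinstance(seqs, dict):
        seqs = seqs.values()
    counts = np.zeros(4)
    for s in seqs:
        s = s.upper()
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    total = counts.sum()
    if total == 0:
        raise ValueError("sequences contain no unambiguous A/C/G/T bases")
    return counts / total


def score_window(pwm: PWM, window: str) -> float:
    """Log-likelihood-ratio score (nats) of one window of length L."""
    window = window.upper()
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    try:
        idx = [_BASE_INDEX[b] for b in window]
    except KeyError as e:
        raise AmbiguousBaseError(f"ambiguous base {e.args[0]!r} in window") from None
    lo = pwm.log_odds
    return float(lo[np.arange(pwm.length), idx].sum())


def apply_variant(seq: str, seq_start: int, v: Variant) -> tuple[str, Locus, Locus]:
    """Apply a variant to ``seq`` (whose first base sits at 1-based
    genomic position ``seq_start``).

    Returns ``(alt_seq, ref_locus, alt_locus)`` where the loci give the
    offsets a scanning window must span on the reference and mutated
    sequences respectively: SNV -> the substituted base(s); insertion -> the
    inserted bases plus both flanking junction bases; deletion -> the deleted
    bases on the reference, the retained-flank junction on the mutated
    sequence.
    """
    seq = seq.upper()
    pos, ref, alt = v.normalized()
    off = pos - seq_start
    if ref:
        if off < 0 or off + len(ref) > len(seq):
            raise ValueError(f"variant {v.chrom}:{v.pos} outside provided sequence")
        found = seq[off:off + len(ref)]
        if found != ref:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{pos}: sequence has "
                f"{found!r}, variant says {ref!r}"
            )
    if ref and alt:  # substitution (SNV or MNV)
        alt_seq = seq[:off] + alt + seq[off + len(ref):]
        ref_locus = Locus(tuple(range(off, off + len(ref))))
        alt_locus = Locus(tuple(range(off, off + len(alt))))
    elif ref and not alt:  # deletion
        if off == 0 or off + len(ref) >= len(seq):
            raise ValueError(
                f"deletion at {v.chrom}:{pos} needs at least one retained base "
                "on each side within the provided sequence"
            )
        alt_seq = seq[:off] + seq[off + len(ref):]
        ref_locus = Locus(tuple(range(off, off + len(ref))))
        alt_locus = Locus((off - 1, off), junction=True)
    else:  # pure insertion after base (pos-1)
        if off < 1 or off > len(seq) - 1:
            raise ValueError(
                f"insertion at {v.chrom}:{pos} needs flanking sequence on both sides"
            )
        alt_seq = seq[:off] + alt + seq[off:]
        ref_locus = Locus((off - 1, off), junction=True)
        alt_locus = Locus(tuple(range(off - 1, off + len(alt) + 1)))
    return alt_seq, ref_locus, alt_locus


def max_spanning_match(pwm: PWM, seq: str, locus: Locus,
                       strands: str = "both") -> MotifHit:
    """Best-scoring window of the PWM that spans the variant locus.

    Both strands are scanned by default; a reverse-strand hit is the score of
    the reverse complement of the forward window, reported at the forward
    start offset.  Ambiguous-base windows are skipped.  Ties break to the
    smaller start offset, then to the + strand.
    """
    L = pwm.length
    seq = seq.upper()
    best: Optional[MotifHit] = None
    strand_list = ["+", "-"] if strands == "both" else [strands]
    for start in range(0, len(seq) - L + 1):
        if not locus.spanned_by(start, L):
            continue
        window = seq[start:start + L]
        for strand in strand_list:
            try:
                raw = score_window(pwm, window if strand == "+" else revcomp(window))
            except AmbiguousBaseError:
                continue
            if best is None or raw > best.raw_score:
                best = MotifHit(pwm.motif_id, start, strand, raw, raw / pwm.max_score)
    if best is None:
        raise NoSpanningWindowError(
            f"no window of PWM {pwm.motif_id} (L={L}) can span the locus in a "
            f"{len(seq)} bp sequence"
        )
    return best


def assign_tier(norm_score: float) -> Optional[int]:
    """Tier 1: norm >= 0.6; Tier 2: 0.45 <= norm < 0.6; else None."""
    if not math.isfinite(norm_score):
        raise ValueError("tier of a non-finite score")
    if norm_score >= TIER1_MIN:
        return 1
    if norm_score >= TIER2_MIN:
        return 2
    return None


def disruption_score(ref_hit: MotifHit, alt_hit: MotifHit) -> float:
    """Reference norm score minus mutated norm score (positive = loss)."""
    if ref_hit.motif_id != alt_hit.motif_id:
        raise ValueError("hits from different PWMs")
    return ref_hit.norm_score - alt_hit.norm_score


_TRAILING_DIGITS = re.compile(r"\d+$")


def family_of(gene_symbol: str) -> str:
    """TF family from gene symbol: strip one trailing digit run, then an
    exposed trailing hyphen; all FOX factors pool into 'FOX'."""
    if not gene_symbol:
        raise ValueError("empty gene symbol")
    s = gene_symbol.upper()
    if s.startswith("FOX"):
        return "FOX"
    s = _TRAILING_DIGITS.sub("", s)
    return s.rstrip("-") or gene_symbol.upper()


@dataclass(frozen=True)
class DisruptionRecord:
    variant: Variant
    motif_id: str
    gene_symbol: str
    family: str
    ref_hit: MotifHit
    alt_hit: MotifHit
    tier: Optional[int]
    disruption: float


@dataclass
class FamilyReport:
    """Per-tier family ranking after collapsing overlapping same-family hits."""

    tier: int
    families: list  # [(family, best DisruptionRecord)] sorted by disruption desc


def rank_disruptions(
    variant: Variant,
    pwms: Sequence[PWM],
    reference: str,
    ref_start: int = 1,
    flank_bp: int = 30,
) -> tuple[list[DisruptionRecord], dict[int, list]]:
    """Score every PWM against a variant and rank disrupted families per tier.

    For each PWM, the maximal locus-spanning match is found on the reference
    and on the mutated sequence; the tier comes from the reference-sequence
    normalised score (a candidate site must exist before it can be
    disrupted), and the disruption is the normalised score difference.
    Within each tier, same-family records whose reference alignments overlap
    are collapsed to a single family entry carrying the maximum disruption.

    Returns ``(records, family_ranking)`` where ``family_ranking[tier]`` is a
    list of ``(family, DisruptionRecord)`` sorted by disruption descending,
    then motif id.
    """
    max_len = max(p.length for p in pwms)
    if flank_bp < max_len:
        raise ValueError(f"flank_bp={flank_bp} smaller than longest PWM ({max_len})")
    pos, ref, alt = variant.normalized()
    lo = max(1, pos - flank_bp)
    hi = min(ref_start + len(reference) - 1, pos + max(len(ref), 1) - 1 + flank_bp)
    if pos < ref_start or pos + max(len(ref), 1) - 1 > ref_start + len(reference) - 1:
        raise ValueError(f"variant {variant.chrom}:{variant.pos} outside reference")
    seq = reference[lo - ref_start: hi - ref_start + 1]
    alt_seq, ref_locus, alt_locus = apply_variant(seq, lo, variant)

    records: list[DisruptionRecord] = []
    for pwm in pwms:
        try:
            ref_hit = max_spanning_match(pwm, seq, ref_locus)
            alt_hit = max_spanning_match(pwm, alt_seq, alt_locus)
        except NoSpanningWindowError:
            continue
        records.append(DisruptionRecord(
            variant=variant,
            motif_id=pwm.motif_id,
            gene_symbol=pwm.gene_symbol,
            family=family_of(pwm.gene_symbol),
            ref_hit=ref_hit,
            alt_hit=alt_hit,
            tier=assign_tier(ref_hit.norm_score),
            disruption=disruption_score(ref_hit, alt_hit),
        ))
    records.sort(key=lambda r: (-r.disruption, r.motif_id))

    pwm_len = {p.motif_id: p.length for p in pwms}
    ranking: dict[int, list] = {}
    for tier in (1, 2):
        tier_recs = [r for r in records if r.tier == tier]
        best_by_family: dict[str, DisruptionRecord] = {}
        for r in tier_recs:
            cur = best_by_family.get(r.family)
            if cur is None:
                best_by_family[r.family] = r
                continue
            # collapse only when reference alignments share at least one base
            a0, a1 = r.ref_hit.start, r.ref_hit.start + pwm_len[r.motif_id]
            b0, b1 = cur.ref_hit.start, cur.ref_hit.start + pwm_len[cur.motif_id]
            if a0 < b1 and b0 < a1:
                if r.disruption > cur.disruption:
                    best_by_family[r.family] = r
            elif r.disruption > cur.disruption:
                # non-overlapping same-family hit: keep the stronger one as
                # the family representative
                best_by_family[r.family] = r
        ranking[tier] = sorted(
            best_by_family.items(), key=lambda kv: (-kv[1].disruption, kv[1].motif_id)
        )
    return records, ranking
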