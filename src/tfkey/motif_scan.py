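"""PWM promoter scanning and ranked TF → target gene set construction.

The central score is the **Jindex**: for a motif of width ``w`` slid along a
promoter of length ``l``, each start ``s`` receives the width-averaged
log-likelihood ratio

    score(s) = (1/w) · Σ_k ln[ q(k, L_{s+k−1}) / p(L_{s+k−1}) ]

where ``q`` is the PWM probability and ``p`` the mononucleotide background
estimated from that promoter sequence itself. The Jindex of a (TF, promoter)
pair is the maximum of score(s) over all starts on both strands; a value
above 1.0 flags a candidate binding site. The legacy **RS** score — the log
of the mean likelihood ratio over all windows — is kept for comparison.

Reverse-strand windows are scored by scanning the reverse-complemented
sequence against the complement-swapped background, which makes the Jindex
exactly invariant under reverse-complementing the whole promoter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ALPHABET",
    "PWM",
    "PromoterRecord",
    "SiteScore",
    "RankedGeneSet",
    "sequence_background",
    "load_promoters",
    "load_jaspar",
    "jindex",
    "rs_score",
    "scan_promoters",
]

ALPHABET = "ACGT"

_CODES = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODES[ord(_b)] = _i
    _CODES[ord(_b.lower())] = _i


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as int8 (A=0, C=1, G=2, T=3; anything else −1)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position nucleotide probabilities.

    ``probs`` has one row per motif position and columns in A, C, G, T order;
    every row must be a strictly positive probability vector.
    """

    tf_id: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", q)
        if q.ndim != 2 or q.shape[1] != 4 or q.shape[0] < 1:
            raise ValueError(f"{self.tf_id}: probs must be (width, 4)")
        if np.any(q <= 0):
            raise ValueError(f"{self.tf_id}: probabilities must be > 0 "
                             "(regularize counts first)")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.tf_id}: position probabilities must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_counts(cls, tf_id: str, counts: np.ndarray,
                    pseudo: float = 0.001) -> "PWM":
        """Build from a JASPAR-style 4 x w count (or frequency) matrix.

        Columns are normalized to probabilities and floored with
        ``q ← (q + pseudo)/(1 + 4·pseudo)`` so logs stay finite.
        """
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError(f"{tf_id}: counts must be (4, width)")
        colsum = c.sum(axis=0)
        if np.any(colsum <= 0):
            raise ValueError(f"{tf_id}: empty count column")
        q = (c / colsum).T
        q = (q + pseudo) / (1.0 + 4.0 * pseudo)
        return cls(tf_id=tf_id, probs=q)


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence with its per-sequence mononucleotide background."""

    gene_id: str
    sequence: str
    background: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", p)
        if p.shape != (4,) or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"{self.gene_id}: invalid background")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.gene_id}: empty sequence")


def sequence_background(gene_id: str, sequence: str,
                        pseudo: float = 1.0) -> PromoterRecord:
    """Estimate the background p(L) from the sequence's own base frequencies.

    N (and any non-ACGT) bases are excluded from counting; the estimate is
    regularized as (count + pseudo)/(effective_length + 4·pseudo).
    """
    codes = encode(sequence)
    counts = np.bincount(codes[codes >= 0], minlength=4).astype(float)
    eff = counts.sum()
    if eff == 0:
        raise ValueError(f"promoter {gene_id!r} contains no A/C/G/T bases")
    p = (counts + pseudo) / (eff + 4.0 * pseudo)
    return PromoterRecord(gene_id=gene_id, sequence=sequence, background=p)


def load_promoters(fasta_path) -> list[PromoterRecord]:
    """Load promoters from FASTA; the record id's first token is the gene id."""
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        records.append(sequence_background(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path!s}")
    return records


def load_jaspar(path, pseudo: float = 0.001) -> list[PWM]:
    """Load PWMs from a JASPAR-format motif file (counts or frequencies)."""
    from Bio import motifs

    pwms = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            tf_id = m.name or m.matrix_id
            pwms.append(PWM.from_counts(str(tf_id), counts, pseudo=pseudo))
    if not pwms:
        raise ValueError(f"no motifs in {path!s}")
    return pwms


@dataclass(frozen=True)
class SiteScore:
    """Best-scoring site of one PWM in one promoter (1-based offset)."""

    tf_id: str
    gene_id: str
    offset: int
    strand: str
    jindex: float
    rs: float = float("nan")


@dataclass(frozen=True)
class RankedGeneSet:
    """TF → {target gene: rank score}; rank score = the gene's best Jindex."""

    tf_id: str
    members: dict[str, float]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _window_means(llr: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Width-averaged LLR per start plus a validity mask (no-N windows)."""
    w = llr.shape[0]
    m = codes.size - w + 1
    valid_pos = codes >= 0
    safe = np.where(valid_pos, codes, 0)
    windows = np.lib.stride_tricks.sliding_window_view(safe, w)
    scores = llr[np.arange(w)[None, :], windows].sum(axis=1) / w
    mask = np.lib.stride_tricks.sliding_window_view(valid_pos, w).all(axis=1)
    return scores, mask


def _strand_scans(pwm: PWM, record: PromoterRecord, both_strands: bool):
    codes = encode(record.sequence)
    if codes.size < pwm.width:
        raise ValueError(
            f"promoter {record.gene_id!r} shorter than motif {pwm.tf_id!r}"
        )
    logq = np.log(pwm.probs)
    fwd = _window_means(logq - np.log(record.background)[None, :], codes)
    out = [("+", *fwd)]
    if both_strands:
        rc = np.where(codes >= 0, 3 - codes, -1)[::-1]
        p_rc = record.background[::-1]  # complement swap: A<->T, C<->G
        out.append(("-", *_window_means(logq - np.log(p_rc)[None, :], rc)))
    return out


def jindex(pwm: PWM, record: PromoterRecord,
           both_strands: bool = True) -> SiteScore:
    """Best width-averaged LLR over all starts (and strands, by default).

    Windows containing N are skipped. Ties at the maximum resolve to the
    forward strand, then to the smallest 1-based forward offset.
    """
    l, w = len(record.sequence), pwm.width
    best: tuple[float, int, int] | None = None  # (score, strand_pref, offset)
    for strand, scores, mask in _strand_scans(pwm, record, both_strands):
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        sub = scores[idx]
        top = sub.max()
        hits = idx[sub == top]
        if strand == "+":
            offset = int(hits.min()) + 1
            pref = 0
        else:
            # reverse-strand start s0 (0-based on the RC) maps to forward
            # 1-based offset l − w − s0 + 1; smallest offset = largest s0
            offset = l - w - int(hits.max()) + 1
            pref = 1
        cand = (float(top), pref, offset)
        if best is None or cand[0] > best[0] or (
            cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])
        ):
            best = cand
    if best is None:
        raise ValueError(
            f"no scorable window for {pwm.tf_id!r} in {record.gene_id!r} "
            "(all windows contain N)"
        )
    return SiteScore(tf_id=pwm.tf_id, gene_id=record.gene_id,
                     offset=best[2], strand="+-"[best[1]], jindex=best[0])


def rs_score(pwm: PWM, record: PromoterRecord) -> float:
    """Legacy raw score RS = ln[(1/M)·Σ_s Π_k q/p] over forward windows.

    M counts the scorable (N-free) windows. With a single window this equals
    the window's summed LLR; in general ln of a mean of likelihood ratios.
    """
    (_, scores, mask), = _strand_scans(pwm, record, both_strands=False)
    if not mask.any():
        raise ValueError(
            f"no scorable window for {pwm.tf_id!r} in {record.gene_id!r}"
        )
    sums = scores[mask] * pwm.width  # per-window Σ_k ln(q/p)
    return float(logsumexp(sums) - np.log(sums.size))


def scan_promoters(
    pwms: Sequence[PWM],
    promoters: Sequence[PromoterRecord],
    threshold: float = 1.0,
    both_strands: bool = True,
    with_rs: bool = True,
) -> tuple[pd.DataFrame, dict[str, RankedGeneSet]]:
    """Scan every promoter with every PWM and emit sites with Jindex ≥ threshold.

    Returns the site table (one row per passing (TF, gene) pair, best site
    only, sorted by tf_id then gene_id) and the ranked gene sets keyed by
    TF id (per-gene rank score = best Jindex). Promoters shorter than a
    motif, or fully N-masked for it, are skipped with a warning.
    """
    if not len(pwms) or not len(promoters):
        raise ValueError("need at least one PWM and one promoter")
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    rows = []
    skipped = 0
    for pwm in sorted(pwms, key=lambda p: p.tf_id):
        for rec in sorted(promoters, key=lambda r: r.gene_id):
            try:
                site = jindex(pwm, rec, both_strands=both_strands)
            except ValueError:
                skipped += 1
                continue
            if site.jindex >= threshold:
                rs = rs_score(pwm, rec) if with_rs else float("nan")
                rows.append((pwm.tf_id, rec.gene_id, site.offset,
                             site.strand, site.jindex, rs))
    if skipped:
        warnings.warn(f"skipped {skipped} unscannable (PWM, promoter) pair(s)",
                      RuntimeWarning, stacklevel=2)
    table = pd.DataFrame(
        rows, columns=["tf_id", "gene_id", "offset", "strand", "jindex", "rs"]
    )
    sets: dict[str, RankedGeneSet] = {}
    for tf_id, sub in table.groupby("tf_id", sort=True):
        members = dict(zip(sub["gene_id"], sub["jindex"].astype(float)))
        sets[str(tf_id)] = RankedGeneSet(tf_id=str(tf_id), members=members)
    return table, sets
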