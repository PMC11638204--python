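"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as plain Python loops against the
formulas, with no imports from the package's scoring internals, so that
agreement is evidence rather than tautology.
"""

import math

import numpy as np

_IDX = {b: i for i, b in enumerate("ACGT")}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_weighted_tau(ranks, v):
    """Double-loop weighted Kendall tau-a over all pairs."""
    ranks = list(ranks)
    v = list(v)
    n = len(ranks)
    s = 0.0
    for i in range(n):
        for j in range(i):
            s += v[i] * v[j] * np.sign(i - j) * np.sign(ranks[i] - ranks[j])
    sv = sum(v)
    sv2 = sum(x * x for x in v)
    return 2.0 * s / (sv * sv - sv2)


def brute_std_tau(ranks):
    return brute_weighted_tau(ranks, [1.0] * len(ranks))


def revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def brute_background(seq, pseudo=1.0):
    """(count + pseudo)/(effective_length + 4*pseudo), N excluded."""
    seq = seq.upper()
    counts = [seq.count(b) for b in "ACGT"]
    eff = sum(counts)
    return [(c + pseudo) / (eff + 4 * pseudo) for c in counts]


def _scan_windows(probs, seq, background):
    """Width-averaged LLR of every N-free window of one strand."""
    w = len(probs)
    out = []
    for start in range(len(seq) - w + 1):
        win = seq[start:start + w]
        if any(b not in _IDX for b in win):
            continue
        score = sum(
            math.log(probs[k][_IDX[win[k]]] / background[_IDX[win[k]]])
            for k in range(w)
        ) / w
        out.append(score)
    return out


def brute_jindex(probs, seq, background=None, both_strands=True):
    """Max width-averaged LLR over all windows/strands by enumeration.

    The reverse strand scans the reverse-complemented sequence against its
    own (complement-swapped) background, independently recomputed here.
    """
    seq = seq.upper()
    if background is None:
        background = brute_background(seq)
        rc_background = None
    else:
        rc_background = list(reversed(background))
    scores = _scan_windows(probs, seq, background)
    if both_strands:
        rc = revcomp(seq)
        if rc_background is None:
            rc_background = brute_background(rc)
        scores += _scan_windows(probs, rc, rc_background)
    if not scores:
        raise ValueError("no scorable window")
    return max(scores)


def brute_rs(probs, seq, background=None):
    """ln of the mean likelihood ratio over forward N-free windows."""
    seq = seq.upper()
    if background is None:
        background = brute_background(seq)
    w = len(probs)
    ratios = []
    for start in range(len(seq) - w + 1):
        win = seq[start:start + w]
        if any(b not in _IDX for b in win):
            continue
        prod = 1.0
        for k in range(w):
            prod *= probs[k][_IDX[win[k]]] / background[_IDX[win[k]]]
        ratios.append(prod)
    return math.log(sum(ratios) / len(ratios))


def brute_vo(px, py, theta, origin=(0.0, 0.0)):
    """Scalar projection of OP onto the axis unit vector (dot product)."""
    return ((px - origin[0]) * math.cos(theta)
            + (py - origin[1]) * math.sin(theta))


def random_pwm_probs(rng, width):
    """Random strictly positive PWM rows summing to one."""
    raw = rng.dirichlet(np.ones(4) * 0.8, size=width)
    raw = (raw + 0.01) / (1.0 + 0.04)
    return raw
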