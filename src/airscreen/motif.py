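"""Position-weight-matrix scanning with exact null-distribution thresholds.

A motif is a PWM over {A, C, G, T}. Sequences are scored by the summed
log2-odds of the PWM against a 0-order background; a site "is present" when
the best window score reaches the threshold at which the exact probability
of such a score under the background model drops below the chosen p (e.g.
p < 1e-4 for a canonical site).

The null score distribution is computed exactly by position-wise convolution
of the per-position score distributions, after discretizing scores to a
fixed step (in bits). This is the standard lattice algorithm used by exact
motif p-value tools; the discretization step bounds the threshold error by
L*step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


@dataclass
class MotifModel:
    """A PWM (L x 4 probabilities, columns A/C/G/T) with a background model."""

    pwm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    name: str = "motif"

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValidationError("pwm: expected an L x 4 matrix (columns A, C, G, T)")
        if self.pwm.shape[0] < 4:
            raise ValidationError(f"pwm: motif length must be >= 4, got {self.pwm.shape[0]}")
        if np.any(self.pwm < 0) or np.any(np.abs(self.pwm.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("pwm: each position must be a probability vector summing to 1")
        if np.any(self.background <= 0) or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValidationError("background: must be positive and sum to 1")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    def log_odds(self) -> np.ndarray:
        """L x 4 log2-odds matrix; a zero 5th column lets ambiguous bases score 0."""
        lo = np.log2(np.maximum(self.pwm, 1e-300) / self.background)
        return np.hstack([lo, np.zeros((self.length, 1))])

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.pwm.argmax(axis=1))

    @classmethod
    def from_consensus(
        cls, consensus: str, p_major: float = 0.91, name: str | None = None
    ) -> "MotifModel":
        """Build a sharp PWM from a consensus string (``p_major`` on the consensus base)."""
        consensus = consensus.upper()
        if set(consensus) - set(ALPHABET):
            raise ValidationError("consensus: must be an A/C/G/T string")
        if not 0.25 < p_major < 1.0:
            raise ValidationError(f"p_major: must be in (0.25, 1), got {p_major}")
        pwm = np.full((len(consensus), 4), (1.0 - p_major) / 3.0)
        for i, base in enumerate(consensus):
            pwm[i, _CODE[base]] = p_major
        return cls(pwm=pwm, name=name or f"consensus:{consensus}")

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 0.5,
        background: np.ndarray | None = None,
        name: str = "motif",
    ) -> "MotifModel":
        """Build from a count matrix (L x 4) with an additive pseudocount."""
        counts = np.asarray(counts, dtype=float)
        if pseudocount < 0:
            raise ValidationError("pseudocount: must be >= 0")
        pwm = counts + pseudocount
        pwm = pwm / pwm.sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": background}
        return cls(pwm=pwm, name=name, **kwargs)


def motif_score_threshold(m: MotifModel, p: float, precision: float = 0.01) -> float:
    """Smallest log2-odds score s with P(score >= s | background) <= p.

    The null distribution is exact up to discretization: per-position scores
    are rounded to a lattice of ``precision`` bits and convolved across
    positions (each position independent under the 0-order background).
    Raises when no achievable score has a tail probability <= p, which
    happens for degenerate motifs (e.g. a PWM equal to the background, where
    every sequence scores 0) or when the lattice is too coarse to separate
    the top scores.
    """
    if not 0.0 < p <= 1.0:
        raise ValidationError(f"p: must be in (0, 1], got {p}")
    if precision <= 0:
        raise ValidationError(f"precision: must be > 0, got {precision}")
    lo = m.log_odds()[:, :4]
    q = np.rint(lo / precision).astype(np.int64)

    # dist maps lattice score -> probability, convolved position by position
    offset = 0  # lattice value of dist[0]
    dist = np.array([1.0])
    for i in range(m.length):
        qmin, qmax = int(q[i].min()), int(q[i].max())
        new = np.zeros(len(dist) + (qmax - qmin))
        for j in range(4):
            new[q[i, j] - qmin : q[i, j] - qmin + len(dist)] += m.background[j] * dist
        dist = new
        offset += qmin

    tail = np.cumsum(dist[::-1])[::-1]  # tail[k] = P(score_lattice >= offset + k)
    # threshold at an ACHIEVABLE score so that exact (unrounded) scan scores
    # falling in the gap below it cannot pass; the half-lattice guard absorbs
    # the per-word rounding error (|exact - lattice| <= L*precision/2)
    ok = np.flatnonzero((tail <= p) & (dist > 0.0))
    if len(ok) == 0:
        raise ValidationError(
            f"no achievable score has tail probability <= {p}: the motif is too "
            f"close to the background or the discretization (step {precision} "
            f"bits) is too coarse; try a smaller precision"
        )
    return float((offset + int(ok[0])) * precision - m.length * precision / 2.0)


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N, ambiguity codes) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(len(arr), 4, dtype=np.int8)
    for base, i in _CODE.items():
        codes[arr == ord(base)] = i
    return codes


def _window_scores(codes: np.ndarray, lo_ext: np.ndarray) -> np.ndarray:
    """Log-odds score of every length-L window of an encoded sequence."""
    length = lo_ext.shape[0]
    n_win = len(codes) - length + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    for j in range(length):
        scores += lo_ext[j, codes[j : j + n_win]]
    return scores


def best_hit(seq: str, m: MotifModel, both_strands: bool = True):
    """Best-scoring site of ``m`` in ``seq``: (position, strand, score) or None.

    The position is the 0-based start of the matched window on the forward
    sequence for either strand. Ties prefer the forward strand, then the
    leftmost position. Ambiguous bases contribute 0 log-odds.
    """
    codes = encode(seq)
    lo_ext = m.log_odds()
    fwd = _window_scores(codes, lo_ext)
    if len(fwd) == 0:
        return None
    candidates = [(float(fwd.max()), "+", int(fwd.argmax()))]
    if both_strands:
        # scoring the reverse complement in place: reverse the PWM and complement columns
        lo_rc = np.ascontiguousarray(lo_ext[::-1][:, _COMPLEMENT])
        rev = _window_scores(codes, lo_rc)
        candidates.append((float(rev.max()), "-", int(rev.argmax())))
    score, strand, pos = max(candidates, key=lambda c: (c[0], c[1] == "+", -c[2]))
    return pos, strand, score
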