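"""Position matrices for splice-site scoring.

A position probability matrix (PPM) gives per-position base frequencies of a
splice-site motif.  It is turned into a log-odds position weight matrix (PWM)
against a uniform background (``log2(p / 0.25)``), scored by summing the
per-position entries of a window, and the raw score ``m`` is rescaled onto a
0-100 scale anchored at the least (0), neutral (50) and best (100) achievable
windows:

    x = 50 * (m - m_min) / (-m_min)   for m < 0
    x = 50 + 50 * m / m_max           for m >= 0

Zero probabilities are replaced by a small pseudocount before the log
transform so no window scores -inf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: width of the donor (5'SS) window: 3 exonic + 9 intronic nt (-3..+9)
DONOR_WIDTH = 12
#: width of the acceptor (3'SS) window: 13 intronic + 1 exonic nt (-13..+1)
ACCEPTOR_WIDTH = 14
#: width of one branch-point window
BPS_WIDTH = 12
#: scan region upstream of the 3'SS for branch points (-40..-1)
BPS_REGION = 40
#: number of sliding branch-point windows in a full-length region
N_BPS_WINDOWS = BPS_REGION - BPS_WIDTH + 1  # 29

DEFAULT_PSEUDOCOUNT = 0.0001

#: canonical matrix names used throughout the package
PPM_NAMES_5SS = (
    "minor_5ss_ATAC",
    "minor_5ss_GTAG",
    "major_5ss_GTAG",
    "major_5ss_GCAG",
)
PPM_NAMES_3SS = ("minor_3ss_ATAC", "minor_3ss_GTAG")
PPM_NAMES_BPS = ("bps_A9", "bps_A10")


@dataclass
class Ppm:
    """Position probability matrix: rows A,C,G,T x columns = positions."""

    name: str
    matrix: np.ndarray  # shape (4, width)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValueError(f"PPM {self.name}: expected a 4 x width matrix")
        if (self.matrix < 0).any():
            raise ValueError(f"PPM {self.name}: negative probability")
        sums = self.matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"PPM {self.name}: column {bad + 1} sums to {sums[bad]:.6f}, not 1"
            )

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


@dataclass
class Pwm:
    """Log-odds matrix with its achievable raw-score range."""

    name: str
    matrix: np.ndarray  # shape (4, width), log2 odds
    m_min: float = field(init=False)
    m_max: float = field(init=False)
    ambiguous_value: np.ndarray = field(init=False)  # per-column score for N etc.

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.m_min = float(self.matrix.min(axis=0).sum())
        self.m_max = float(self.matrix.max(axis=0).sum())
        # ambiguity codes score like a pseudocount base: the column minimum,
        # the most conservative assignment
        self.ambiguous_value = self.matrix.min(axis=0)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))


def build_pwm(ppm: Ppm, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> Pwm:
    """Log-odds transform of a PPM against the uniform background.

    Zeros are replaced by `pseudocount` before taking ``log2(p / 0.25)``.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    probs = ppm.matrix.copy()
    probs[probs == 0] = pseudocount
    return Pwm(name=ppm.name, matrix=np.log2(probs / 0.25))


def raw_score(window: str, pwm: Pwm, max_ambiguous: int = 2) -> float:
    """Sum the per-position log-odds entries of `window`.

    Ambiguity codes (N etc.) take the column's most conservative (minimum)
    value; windows with more than `max_ambiguous` ambiguous bases raise.
    """
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} != PWM {pwm.name} width {pwm.width}"
        )
    window = window.upper()
    m = 0.0
    n_ambig = 0
    for j, base in enumerate(window):
        i = BASE_INDEX.get(base)
        if i is None:
            n_ambig += 1
            m += pwm.ambiguous_value[j]
        else:
            m += pwm.matrix[i, j]
    if n_ambig > max_ambiguous:
        raise AmbiguousWindowError(
            f"window has {n_ambig} ambiguous bases (limit {max_ambiguous})"
        )
    return m


class AmbiguousWindowError(ValueError):
    """Window contains too many non-ACGT bases to be scorable."""


def rescale_score(m: float, pwm: Pwm) -> float:
    """Map a raw score onto 0-100 with fixed points m_min->0, 0->50, m_max->100."""
    if pwm.m_min == 0 or pwm.m_max == 0:
        raise ValueError(f"degenerate matrix {pwm.name}: m_min or m_max is zero")
    if not np.isfinite(m):
        raise ValueError("raw score must be finite")
    if m < pwm.m_min or m > pwm.m_max:
        warnings.warn(
            f"raw score {m:.3f} outside [{pwm.m_min:.3f}, {pwm.m_max:.3f}] "
            f"for {pwm.name}; clamping",
            stacklevel=2,
        )
    if m < 0:
        x = 50.0 * (m - pwm.m_min) / (-pwm.m_min)
    else:
        x = 50.0 + 50.0 * m / pwm.m_max
    return float(min(100.0, max(0.0, x)))


def score_window(window: str, pwm: Pwm) -> float:
    """Raw-score then rescale `window` against `pwm`."""
    return rescale_score(raw_score(window, pwm), pwm)


def best_bps_score(
    bps_windows: list[str], pwm_a9: Pwm, pwm_a10: Pwm
) -> tuple[float, int, str] | None:
    """Best rescaled branch-point score over all windows and both A9/A10 variants.

    Returns ``(score, window_index_1based, variant)``; ties go to the smaller
    window index, then to A9.  Returns None when no window is scorable.
    """
    best: tuple[float, int, str] | None = None
    for idx, window in enumerate(bps_windows, start=1):
        for variant, pwm in (("A9", pwm_a9), ("A10", pwm_a10)):
            try:
                x = score_window(window, pwm)
            except (AmbiguousWindowError, ValueError):
                continue
            if best is None or x > best[0]:
                best = (x, idx, variant)
    return best


# ---------------------------------------------------------------------------
# SpliceRack-style serialization: whitespace-delimited text, one row per base
# A/C/G/T, columns = positions; '>' header lines carry the matrix name.
# ---------------------------------------------------------------------------


def write_ppms(ppms: dict[str, Ppm], path: str) -> None:
    with open(path, "w") as fh:
        for name in ppms:
            ppm = ppms[name]
            fh.write(f">{name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{v:.6f}" for v in ppm.matrix[i])
                fh.write(f"{base} {row}\n")


def read_ppms(path: str) -> dict[str, Ppm]:
    """Load a SpliceRack-style PPM text file; validates column sums."""
    ppms: dict[str, Ppm] = {}
    name: str | None = None
    rows: dict[str, list[float]] = {}

    def _flush() -> None:
        nonlocal name, rows
        if name is None:
            return
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise ValueError(f"PPM {name}: missing rows for {missing}")
        ppms[name] = Ppm(name=name, matrix=np.array([rows[b] for b in BASES]))
        name, rows = None, {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].strip()
                continue
            parts = line.split()
            base = parts[0].upper()
            if base not in BASE_INDEX:
                raise ValueError(f"{path}:{lineno}: unexpected row label {parts[0]!r}")
            if name is None:
                raise ValueError(f"{path}:{lineno}: matrix row before any '>' header")
            rows[base] = [float(v) for v in parts[1:]]
    _flush()
    return ppms


@dataclass
class PwmSet:
    """The named PWM collection the classifier needs."""

    pwms: dict[str, Pwm]

    @classmethod
    def from_ppms(
        cls, ppms: dict[str, Ppm], pseudocount: float = DEFAULT_PSEUDOCOUNT
    ) -> "PwmSet":
        required = set(PPM_NAMES_5SS) | set(PPM_NAMES_3SS) | set(PPM_NAMES_BPS)
        missing = required - set(ppms)
        if missing:
            raise ValueError(f"missing PPMs: {sorted(missing)}")
        return cls({name: build_pwm(ppm, pseudocount) for name, ppm in ppms.items()})

    @classmethod
    def from_file(cls, path: str, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "PwmSet":
        return cls.from_ppms(read_ppms(path), pseudocount)

    def __getitem__(self, name: str) -> Pwm:
        return self.pwms[name]
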