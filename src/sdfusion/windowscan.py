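"""Sliding-window divergence profiles and NAHR breakpoint localization.

Nucleotide diversity pi between two aligned haplotypes is computed in
sliding windows (default 500 b window, 100 b step). Columns where either
base is a gap or N are excluded from both numerator and denominator; a
window with no comparable site reports pi as undefined (NaN), never 0.
Only full windows are scanned; a trailing partial window is dropped.

Gene-conversion tracts appear as runs of windows whose SD1-vs-SD2 pi falls
well below the profile median ("islands" of paralog identity). The fusion
breakpoint of a chimeric haplotype is localized by a prefix-sum scan over
all candidate switch points b: total(b) = mismatches(fused[0:b], SD1[0:b])
+ mismatches(fused[b:L], SD2[b:L]). Because the paralogs are locally
identical around the true breakpoint, the argmin is a plateau, reported as
a half-open interval rather than a point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from sdfusion.alignment import SDRecord, encode

__all__ = [
    "ScanConfig",
    "DivergenceProfile",
    "ConversionTract",
    "BreakpointInterval",
    "window_pi",
    "detect_conversion_tracts",
    "locate_breakpoint",
    "species_breakpoint_interval",
    "profile_switch_curves",
]


@dataclass(frozen=True)
class ScanConfig:
    window: int = 500
    step: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError(f"need 0 < step <= window, got step={self.step}, window={self.window}")


def _codes(seq) -> np.ndarray:
    if isinstance(seq, SDRecord):
        return seq.codes()
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8)
    return encode(str(seq))


def _label(seq, default: str) -> str:
    return seq.label if isinstance(seq, SDRecord) else default


@dataclass
class DivergenceProfile:
    """Windowed pi between one pair of aligned haplotypes.

    ``pi`` is NaN where a window has no comparable site (flagged undefined).
    """

    pair: tuple[str, str]
    starts: np.ndarray
    ends: np.ndarray
    pi: np.ndarray
    n_compared: np.ndarray

    @property
    def windows(self) -> list[tuple[int, int, float, int]]:
        return list(zip(self.starts.tolist(), self.ends.tolist(),
                        self.pi.tolist(), self.n_compared.tolist()))

    def __len__(self) -> int:
        return self.starts.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start": self.starts, "end": self.ends, "pi": self.pi,
             "n_compared": self.n_compared}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ConversionTract:
    """A putative gene-conversion tract: a run of low-pi windows."""

    start: int
    end: int
    mean_pi_inside: float
    mean_pi_outside: float


@dataclass(frozen=True)
class BreakpointInterval:
    """Half-open span of switch points minimizing total fused-vs-flank mismatches.

    ``multimodal`` is set when the argmin set is non-contiguous; the interval
    is then the smallest enclosing span.
    """

    start: int
    end: int
    min_mismatches: int
    multimodal: bool = False

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


def window_pi(a, b, cfg: ScanConfig = ScanConfig()) -> DivergenceProfile:
    """Windowed pairwise nucleotide diversity between two aligned sequences.

    Accepts sequence strings, code arrays or :class:`SDRecord`s. Per full
    window, pi = mismatches / comparable sites, where a site is comparable
    when both bases are in {A, C, G, T}.
    """
    ca, cb = _codes(a), _codes(b)
    if ca.size != cb.size:
        raise ValueError(f"aligned lengths differ: {ca.size} != {cb.size}")
    L = ca.size
    if cfg.window > L:
        raise ValueError(f"window {cfg.window} exceeds alignment length {L}")

    comparable = (ca < 4) & (cb < 4)
    diff = comparable & (ca != cb)
    # prefix sums: counts over [0, i)
    comp_ps = np.concatenate([[0], np.cumsum(comparable)])
    diff_ps = np.concatenate([[0], np.cumsum(diff)])

    starts = np.arange(0, L - cfg.window + 1, cfg.step)
    ends = starts + cfg.window
    n_comp = comp_ps[ends] - comp_ps[starts]
    n_diff = diff_ps[ends] - diff_ps[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n_comp > 0, n_diff / np.maximum(n_comp, 1), np.nan)
    return DivergenceProfile(
        pair=(_label(a, "a"), _label(b, "b")),
        starts=starts,
        ends=ends,
        pi=pi.astype(float),
        n_compared=n_comp.astype(int),
    )


def detect_conversion_tracts(
    profile: DivergenceProfile, low_frac: float = 0.5, min_windows: int = 2
) -> list[ConversionTract]:
    """Find maximal runs of consecutive low-pi windows in an SD1-vs-SD2 profile.

    A window is "low" when its pi is strictly below ``low_frac`` times the
    median pi over all defined windows; maximal runs of at least
    ``min_windows`` consecutive low windows become tracts reported as
    [first window start, last window end). Because windows overlap
    (step < window), runs separated by a single noisy window produce
    overlapping spans; such spans are merged into one tract.
    """
    pi = profile.pi
    defined = ~np.isnan(pi)
    if not defined.any():
        raise ValueError("profile has no defined windows")
    med = float(np.median(pi[defined]))
    low = defined & (pi < low_frac * med)

    runs: list[tuple[int, int]] = []  # window-index runs [i, j]
    i = 0
    n = low.size
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            if j - i + 1 >= min_windows:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1

    # merge runs whose [start, end) spans overlap
    merged: list[tuple[int, int]] = []
    for i, j in runs:
        if merged and profile.starts[i] < profile.ends[merged[-1][1]]:
            merged[-1] = (merged[-1][0], j)
        else:
            merged.append((i, j))

    tracts: list[ConversionTract] = []
    for i, j in merged:
        inside = slice(i, j + 1)
        mask_out = defined.copy()
        mask_out[inside] = False
        tracts.append(
            ConversionTract(
                start=int(profile.starts[i]),
                end=int(profile.ends[j]),
                mean_pi_inside=float(np.nanmean(pi[inside])),
                mean_pi_outside=float(np.mean(pi[mask_out])) if mask_out.any() else float("nan"),
            )
        )
    return tracts


def locate_breakpoint(fused, sd1, sd2, slack: int = 0) -> BreakpointInterval:
    """Localize the SD1->SD2 switch point of a fused haplotype.

    Evaluates total(b) = mismatches(fused[0:b], sd1[0:b]) +
    mismatches(fused[b:L], sd2[b:L]) for every b in [0, L] with one O(L)
    prefix-sum pass and returns the contiguous span of argmin positions
    (ties form a plateau wherever the flanking paralogs are locally
    identical). A non-contiguous optimum set yields the smallest enclosing
    span with ``multimodal=True``.

    With ``slack > 0`` the interval instead spans every b whose total is
    within ``slack`` of the minimum: a single substitution that arose on a
    reference or fused haplotype after the fusion shifts the strict argmin
    past the true switch point, so a noise-tolerant breakpoint *region*
    admits near-optimal switch points (``min_mismatches`` still reports
    the minimum itself).
    """
    cf, c1, c2 = _codes(fused), _codes(sd1), _codes(sd2)
    if not (cf.size == c1.size == c2.size):
        raise ValueError("fused, sd1 and sd2 must share the alignment length")
    if slack < 0:
        raise ValueError("slack must be >= 0")

    mis1 = (cf < 4) & (c1 < 4) & (cf != c1)
    mis2 = (cf < 4) & (c2 < 4) & (cf != c2)
    ps1 = np.concatenate([[0], np.cumsum(mis1)])  # mismatches to SD1 in [0, b)
    ps2 = np.concatenate([[0], np.cumsum(mis2)])
    total = ps1 + (ps2[-1] - ps2)  # total(b), b = 0..L

    m = int(total.min())
    optimal = np.flatnonzero(total <= m + slack)
    start, stop = int(optimal[0]), int(optimal[-1])
    contiguous = optimal.size == (stop - start + 1)
    return BreakpointInterval(
        start=start, end=stop + 1, min_mismatches=m, multimodal=not contiguous
    )


def species_breakpoint_interval(
    fused_haps, sd1, sd2, slack: int = 1
) -> BreakpointInterval:
    """Consensus breakpoint region of a species from all its fused haplotypes.

    Every fused haplotype of a species derives from the same NAHR event, so
    the species-level estimate is the smallest span enclosing each
    haplotype's near-optimal switch interval (default ``slack=1``,
    tolerating one post-fusion substitution per comparison).
    ``min_mismatches`` is the best single-haplotype minimum; ``multimodal``
    is set when the per-haplotype intervals do not all mutually overlap.
    """
    fused_haps = list(fused_haps)
    if not fused_haps:
        raise ValueError("no fused haplotypes supplied")
    ivs = [locate_breakpoint(h, sd1, sd2, slack=slack) for h in fused_haps]
    start = min(iv.start for iv in ivs)
    end = max(iv.end for iv in ivs)
    overlap_all = max(iv.start for iv in ivs) < min(iv.end for iv in ivs)
    return BreakpointInterval(
        start=start,
        end=end,
        min_mismatches=min(iv.min_mismatches for iv in ivs),
        multimodal=not overlap_all or any(iv.multimodal for iv in ivs),
    )


def profile_switch_curves(
    fused, sd1, sd2, cfg: ScanConfig = ScanConfig()
) -> tuple[DivergenceProfile, DivergenceProfile]:
    """The two windowed pi curves (fused vs SD1, fused vs SD2).

    Upstream of the fusion breakpoint the first curve runs near zero and
    the second near the paralog divergence; the curves cross at the
    breakpoint.
    """
    return window_pi(fused, sd1, cfg), window_pi(fused, sd2, cfg)
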