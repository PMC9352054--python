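"""Nonparametric statistics and light-stimulus event-window analysis.

Feature distributions are heavy-tailed and fail Shapiro-Wilk normality, so
all comparisons are nonparametric:

* SMD (standardized median difference) barcodes summarize each treated
  feature distribution against its control:
  SMD = (median(sample) - median(control)) / s_pool with
  s_pool = sqrt((s1^2 + s2^2) / 2) and s = 1.4826 * MAD per group (a robust
  scale consistent with the median numerator; a classical-SD variant is
  available via ``robust=False``).
* Across body segments (paired by frame): Wilcoxon signed-rank, alpha 0.05.
* Drug vs control per feature: Mann-Whitney U with Bonferroni correction over
  the 25-feature panel (alpha = 0.05/25 = 0.002); effect size U / (n1*n2).
* Per-video state/cluster usage percentages: Mann-Whitney U at alpha 0.05.

The light-stimulus design presents a 60-s colored-light window starting at
30 s. Responses are measured as per-feature SMDs between a 10-s window before
each event and a 2.5-s window starting 0.5 s after it, separately for light
ON and light OFF (the post-event skip applies to both).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import PANEL_COLUMNS
from .io_model import StimulusProtocol

SHAPIRO_MAX_N = 4999  # larger samples are deterministically subsampled


@dataclass(frozen=True)
class ComparisonResult:
    name: str
    n1: int
    n2: int
    statistic: float
    p_two_sided: float
    p_less: float
    p_greater: float
    effect_size: float | None
    alpha: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class EventWindows:
    """Frame ranges (half-open, start-inclusive) around stimulus ON and OFF."""

    before_on: tuple[int, int]
    after_on: tuple[int, int]
    before_off: tuple[int, int]
    after_off: tuple[int, int]


# ---------------------------------------------------------------------------
# effect sizes and tests
# ---------------------------------------------------------------------------


def _robust_scale(x: np.ndarray) -> float:
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def smd(sample: np.ndarray, control: np.ndarray, robust: bool = True) -> float:
    """Standardized median difference of a sample vs its control.

    (median(sample) - median(control)) / s_pool, s_pool the root mean square
    of the two groups' scales (MAD-based by default). Antisymmetric in its
    arguments. Returns NaN with a warning-free flag semantics when both
    scales are zero (undefined scale).
    """
    a = np.asarray(sample, dtype=float)
    b = np.asarray(control, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if robust:
        s1, s2 = _robust_scale(a), _robust_scale(b)
    else:
        s1 = float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
        s2 = float(np.std(b, ddof=1)) if len(b) > 1 else 0.0
    s_pool = np.sqrt((s1**2 + s2**2) / 2.0)
    diff = float(np.median(a) - np.median(b))
    if s_pool == 0:
        return 0.0 if diff == 0 else np.nan
    return diff / s_pool


def normality(sample: np.ndarray, alpha: float = 0.05, seed: int = 0) -> dict:
    """Shapiro-Wilk normality test. Samples beyond the test's valid range are
    subsampled (seeded) to SHAPIRO_MAX_N; n < 3 is an error."""
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    subsampled = len(x) > SHAPIRO_MAX_N
    if subsampled:
        x = np.random.default_rng(seed).choice(x, SHAPIRO_MAX_N, replace=False)
    stat, p = stats.shapiro(x)
    return {
        "statistic": float(stat),
        "p": float(p),
        "reject_normality": bool(p < alpha),
        "alpha": alpha,
        "n": len(x),
        "subsampled": subsampled,
    }


def paired_segment_test(
    by_segment: dict[str, np.ndarray],
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Wilcoxon signed-rank over all segment pairs (paired by frame).

    Two-sided plus both one-sided p values per pair. All-zero differences
    yield a degenerate flag (two-sided p reported as 1).
    """
    names = list(by_segment)
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a = np.asarray(by_segment[names[i]], dtype=float)
            b = np.asarray(by_segment[names[j]], dtype=float)
            if len(a) != len(b):
                raise ValueError("paired samples must have equal length")
            keep = np.isfinite(a) & np.isfinite(b)
            a, b = a[keep], b[keep]
            if np.all(a == b):
                results.append(
                    ComparisonResult(
                        name=f"{names[i]}_vs_{names[j]}",
                        n1=len(a),
                        n2=len(b),
                        statistic=np.nan,
                        p_two_sided=1.0,
                        p_less=1.0,
                        p_greater=1.0,
                        effect_size=None,
                        alpha=alpha,
                        significant=False,
                        degenerate=True,
                    )
                )
                continue
            two = stats.wilcoxon(a, b, alternative="two-sided")
            less = stats.wilcoxon(a, b, alternative="less")
            greater = stats.wilcoxon(a, b, alternative="greater")
            results.append(
                ComparisonResult(
                    name=f"{names[i]}_vs_{names[j]}",
                    n1=len(a),
                    n2=len(b),
                    statistic=float(two.statistic),
                    p_two_sided=float(two.pvalue),
                    p_less=float(less.pvalue),
                    p_greater=float(greater.pvalue),
                    effect_size=None,
                    alpha=alpha,
                    significant=bool(two.pvalue < alpha),
                )
            )
    return results


def drug_vs_control_test(
    sample: np.ndarray,
    control: np.ndarray,
    name: str = "",
    n_features: int = 25,
    base_alpha: float = 0.05,
) -> ComparisonResult:
    """Mann-Whitney U of a treated feature distribution vs control, at the
    Bonferroni-corrected alpha = base_alpha / n_features (0.002 for the
    25-feature panel). Effect size = U / (n1 * n2)."""
    a = np.asarray(sample, dtype=float)
    b = np.asarray(control, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    alpha = base_alpha / n_features
    two = stats.mannwhitneyu(a, b, alternative="two-sided")
    less = stats.mannwhitneyu(a, b, alternative="less")
    greater = stats.mannwhitneyu(a, b, alternative="greater")
    return ComparisonResult(
        name=name,
        n1=len(a),
        n2=len(b),
        statistic=float(two.statistic),
        p_two_sided=float(two.pvalue),
        p_less=float(less.pvalue),
        p_greater=float(greater.pvalue),
        effect_size=float(two.statistic) / (len(a) * len(b)),
        alpha=alpha,
        significant=bool(two.pvalue < alpha),
    )


def usage_comparison(
    usage_pct: np.ndarray,
    control_pct: np.ndarray,
    name: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Mann-Whitney U on the per-video usage percentages of one state/cluster
    under treatment vs control (alpha 0.05, uncorrected)."""
    a = np.asarray(usage_pct, dtype=float)
    b = np.asarray(control_pct, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 videos per arm")
    two = stats.mannwhitneyu(a, b, alternative="two-sided")
    less = stats.mannwhitneyu(a, b, alternative="less")
    greater = stats.mannwhitneyu(a, b, alternative="greater")
    return ComparisonResult(
        name=name,
        n1=len(a),
        n2=len(b),
        statistic=float(two.statistic),
        p_two_sided=float(two.pvalue),
        p_less=float(less.pvalue),
        p_greater=float(greater.pvalue),
        effect_size=float(two.statistic) / (len(a) * len(b)),
        alpha=alpha,
        significant=bool(two.pvalue < alpha),
    )


# ---------------------------------------------------------------------------
# light-stimulus event windows
# ---------------------------------------------------------------------------

BEFORE_WINDOW_S = 10.0
AFTER_SKIP_S = 0.5
AFTER_WINDOW_S = 2.5


def event_windows(protocol: StimulusProtocol, n_frames: int | None = None) -> EventWindows:
    """Frame windows around stimulus ON/OFF: [event-10 s, event) before and
    [event+0.5 s, event+3.0 s) after, at the protocol's frame rate.

    For the standard design (ON at 30 s, 30 fps): before_on = [600, 900),
    after_on = [915, 990).
    """
    fps = protocol.fps
    on = protocol.onset_s
    off = protocol.offset_s

    def f(sec: float) -> int:
        return int(round(sec * fps))

    win = EventWindows(
        before_on=(f(on - BEFORE_WINDOW_S), f(on)),
        after_on=(f(on + AFTER_SKIP_S), f(on + AFTER_SKIP_S + AFTER_WINDOW_S)),
        before_off=(f(off - BEFORE_WINDOW_S), f(off)),
        after_off=(f(off + AFTER_SKIP_S), f(off + AFTER_SKIP_S + AFTER_WINDOW_S)),
    )
    if win.before_on[0] < 0:
        raise ValueError("recording does not span the before-ON window")
    if n_frames is not None and win.after_off[1] > n_frames:
        raise ValueError(f"recording of {n_frames} frames too short for the after-OFF window")
    return win


def event_response(
    panel: pd.DataFrame,
    windows: EventWindows,
    robust: bool = True,
) -> pd.DataFrame:
    """Per-feature SMD (after - before) around the ON and OFF events.

    ``panel`` is a 25-feature frame-indexed table (see feature_panel); rows
    are selected by position within the recording. Features whose windows are
    entirely masked yield NaN.
    """
    cols = [c for c in PANEL_COLUMNS if c in panel.columns]
    if not cols:
        raise ValueError("panel has no recognized feature columns")
    out = {}
    for event, (before, after) in (
        ("on", (windows.before_on, windows.after_on)),
        ("off", (windows.before_off, windows.after_off)),
    ):
        values = {}
        for c in cols:
            b = panel[c].to_numpy()[before[0] : before[1]]
            a = panel[c].to_numpy()[after[0] : after[1]]
            b, a = b[np.isfinite(b)], a[np.isfinite(a)]
            values[c] = smd(a, b, robust=robust) if len(a) and len(b) else np.nan
        out[event] = values
    return pd.DataFrame(out)


def smd_barcode(
    panels_by_condition: dict[str, pd.DataFrame],
    control_map: dict[str, str],
    robust: bool = True,
) -> pd.DataFrame:
    """Feature x condition grid of SMD values vs each condition's control —
    the barcode summarizing a pharmacological screen."""
    rows = {}
    for cond, ctrl in control_map.items():
        sample = panels_by_condition[cond]
        control = panels_by_condition[ctrl]
        cols = [c for c in PANEL_COLUMNS if c in sample.columns and c in control.columns]
        rows[cond] = {
            c: smd(sample[c].dropna().to_numpy(), control[c].dropna().to_numpy(), robust=robust) for c in cols
        }
    return pd.DataFrame(rows).T
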