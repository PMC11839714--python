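"""Treatment-group statistics: Duncan's multiple range test, dose-response
tables with threshold/saturation detection, and the tissue-by-site summary.

Per-cell integrity scores are grouped by (tissue, site, fraction, dose).
Group means are compared with Duncan's multiple range test: after a one-way
ANOVA, ordered group means are compared stepwise, a pair differing when its
range exceeds the least significant range

    R_p = q(1 - (1-alpha)**(p-1); p, df) * sqrt(MSE / n_h),

where ``p`` is the span of the ordered means covered by the pair, ``q`` the
studentized-range quantile at Duncan's protection level, ``df`` the ANOVA
error degrees of freedom and ``n_h`` the harmonic mean group size.  Results
are reported as a compact letter display (groups sharing a letter do not
differ at level alpha).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TreatmentGroup",
    "GroupSummary",
    "DoseResponseTable",
    "HeatmapSummary",
    "summarize_group",
    "duncan_mrt",
    "dose_response",
    "heatmap_summary",
]

# Colour-scale anchors of the integrity heat map: complete elimination / intact.
SCORE_ELIMINATED = 30.0
SCORE_INTACT = 60.0


@dataclass
class TreatmentGroup:
    """Per-cell scores sharing one (tissue, site, fraction, dose) condition."""

    scores: np.ndarray
    tissue: str = ""
    site: str = ""
    fraction: str = ""
    dose: float = 0.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.size == 0:
            raise ValueError("a group needs a 1-D, non-empty score vector")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n(self) -> int:
        return int(self.scores.size)

    @property
    def label(self) -> tuple:
        return (self.tissue, self.site, self.fraction, self.dose)


@dataclass
class GroupSummary:
    mean: float
    se: float
    n: int
    letter: str = ""


def summarize_group(group: TreatmentGroup) -> GroupSummary:
    """Mean and standard error (sample SD / sqrt(n)) of a group."""
    if group.n < 2:
        raise ValueError("summary requires at least two scores")
    scores = group.scores
    return GroupSummary(
        mean=float(scores.mean()),
        se=float(scores.std(ddof=1) / np.sqrt(group.n)),
        n=group.n,
    )


def _least_significant_ranges(n_means: int, df: int, mse: float, n_h: float,
                              alpha: float) -> np.ndarray:
    """R_p for spans p = 2..n_means (index p-2)."""
    ps = np.arange(2, n_means + 1)
    protection = 1.0 - (1.0 - alpha) ** (ps - 1)
    q = stats.studentized_range.ppf(1.0 - protection, ps, df)
    return q * np.sqrt(mse / n_h)


def duncan_mrt(groups: list[TreatmentGroup], alpha: float = 0.05) -> list[str]:
    """Duncan's multiple range test; returns one letter string per group.

    Groups sharing any letter are not significantly different at ``alpha``.
    The stepwise protection rule applies: a pair inside a span already found
    homogeneous is never declared different.  Letters are assigned in order
    of ascending group mean.
    """
    if len(groups) < 2:
        raise ValueError("Duncan's test needs at least two groups")
    if any(g.n < 2 for g in groups):
        raise ValueError("every group needs at least two scores")

    means = np.array([g.scores.mean() for g in groups])
    ns = np.array([g.n for g in groups], dtype=float)
    k = len(groups)
    big_n = int(ns.sum())
    df = big_n - k
    sse = sum(float(((g.scores - g.scores.mean()) ** 2).sum()) for g in groups)
    mse = sse / df
    n_h = k / float((1.0 / ns).sum())

    order = np.argsort(means, kind="stable")
    sorted_means = means[order]

    if mse <= 0.0:
        # degenerate: no within-group spread; exact mean ties share a letter
        homogeneous = [(i, j) for i in range(k) for j in range(i + 1, k)
                       if np.isclose(sorted_means[i], sorted_means[j])]
    else:
        ranges = _least_significant_ranges(k, df, mse, n_h, alpha)
        homogeneous = []

        def contained(lo: int, hi: int) -> bool:
            return any(a <= lo and hi <= b for a, b in homogeneous)

        # test spans from widest to narrowest; skip protected sub-spans
        for span in range(k, 1, -1):
            for lo in range(0, k - span + 1):
                hi = lo + span - 1
                if contained(lo, hi):
                    continue
                if sorted_means[hi] - sorted_means[lo] <= ranges[span - 2]:
                    homogeneous.append((lo, hi))

    # compact letter display: one letter per maximal homogeneous interval,
    # singleton letters for groups in none
    maximal = [iv for iv in homogeneous
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1]
                          for o in homogeneous)]
    maximal.sort()
    letters_sorted: list[str] = ["" for _ in range(k)]
    alphabet = string.ascii_lowercase
    next_letter = 0

    def take_letter() -> str:
        nonlocal next_letter
        if next_letter < len(alphabet):
            lab = alphabet[next_letter]
        else:  # fall back to aa, ab, ... for very many groups
            lab = alphabet[next_letter // 26 - 1] + alphabet[next_letter % 26]
        next_letter += 1
        return lab

    covered = set()
    for lo, hi in maximal:
        lab = take_letter()
        for i in range(lo, hi + 1):
            letters_sorted[i] += lab
            covered.add(i)
    for i in range(k):
        if i not in covered:
            letters_sorted[i] += take_letter()
    # re-sort each group's letters for a canonical display
    letters_sorted = ["".join(sorted(s)) for s in letters_sorted]

    out = ["" for _ in range(k)]
    for rank, idx in enumerate(order):
        out[idx] = letters_sorted[rank]
    return out


@dataclass
class DoseResponseTable:
    doses: list[float]
    summaries: list[GroupSummary]
    control: GroupSummary
    lowest_significant_dose: float | None
    saturation_dose: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"dose": 0.0, "mean": self.control.mean, "se": self.control.se,
                 "n": self.control.n, "letter": self.control.letter,
                 "is_control": True}]
        rows += [{"dose": d, "mean": s.mean, "se": s.se, "n": s.n,
                  "letter": s.letter, "is_control": False}
                 for d, s in zip(self.doses, self.summaries)]
        return pd.DataFrame(rows)


def dose_response(groups: list[TreatmentGroup], control: TreatmentGroup,
                  alpha: float = 0.05) -> DoseResponseTable:
    """Dose-response table with effect-onset and saturation detection.

    ``lowest_significant_dose`` is the smallest dose sharing no Duncan
    letter with the control; ``saturation_dose`` the smallest dose all
    higher doses share a letter with.
    """
    if len(groups) < 3:
        raise ValueError("dose_response needs at least three dose groups")
    doses = [g.dose for g in groups]
    if any(b <= a for a, b in zip(doses, doses[1:])):
        raise ValueError("groups must be ordered by strictly increasing dose")

    letters = duncan_mrt([control] + groups, alpha=alpha)
    control_summary = summarize_group(control)
    control_summary.letter = letters[0]
    summaries = []
    for g, lab in zip(groups, letters[1:]):
        s = summarize_group(g)
        s.letter = lab
        summaries.append(s)

    lowest = None
    for d, s in zip(doses, summaries):
        if not set(s.letter) & set(control_summary.letter):
            lowest = d
            break

    saturation = None
    if lowest is not None:
        for i, (d, s) in enumerate(zip(doses, summaries)):
            if d < lowest:
                continue
            higher = summaries[i + 1:]
            if all(set(h.letter) & set(s.letter) for h in higher):
                saturation = d  # vacuously the top dose if nothing above it
                break

    return DoseResponseTable(doses=doses, summaries=summaries,
                             control=control_summary,
                             lowest_significant_dose=lowest,
                             saturation_dose=saturation)


@dataclass
class HeatmapSummary:
    """Mean-score matrix (tissue rows x site columns) with the colour anchors."""

    table: pd.DataFrame
    anchor_eliminated: float = SCORE_ELIMINATED
    anchor_intact: float = SCORE_INTACT


def heatmap_summary(groups: list[TreatmentGroup]) -> HeatmapSummary:
    """Tissue x site matrix of mean scores at one fixed dose.

    Missing (tissue, site) cells are NaN, never zero.  Raises if two groups
    claim the same cell.
    """
    seen = {}
    for g in groups:
        key = (g.tissue, g.site)
        if key in seen:
            raise ValueError(f"duplicate group for tissue/site cell {key}")
        seen[key] = float(g.scores.mean())
    tissues = list(dict.fromkeys(g.tissue for g in groups))
    sites = list(dict.fromkeys(g.site for g in groups))
    table = pd.DataFrame(index=tissues, columns=sites, dtype=float)
    for (tissue, site), mean in seen.items():
        table.loc[tissue, site] = mean
    table.index.name = "tissue"
    table.columns.name = "site"
    return HeatmapSummary(table=table)
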