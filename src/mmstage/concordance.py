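"""Between-system stage agreement: cross-tabulation, shift analysis, kappa.

Two staging systems applied to the same cohort yield paired ordinal labels
(stages I-III).  This module builds the 3x3 cross-tabulation, reports
percent agreement and up/down-staging counts, and computes Cohen's weighted
kappa

    kappa = (Po - Pe) / (1 - Pe),
    Po = sum_ij w_ij p_ij,   Pe = sum_ij w_ij p_i. p_.j,

with linear disagreement weights w_ij = 1 - |i-j|/(k-1) by default
(quadratic and unweighted schemes available).  The asymptotic standard
error follows Fleiss, Cohen & Everitt (1969): the non-null variance feeds
the 95% normal CI, the null variance the test of H0: kappa = 0.  Kappa is
0 for agreement at chance level and 1 for perfect agreement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "STAGE_LABELS",
    "CrossTab",
    "KappaResult",
    "build_crosstab",
    "percent_agreement",
    "shift_summary",
    "ShiftSummary",
    "weighted_kappa",
    "kappa_weight_matrix",
]

STAGE_LABELS = ("I", "II", "III")


@dataclass(frozen=True)
class CrossTab:
    """k x k contingency table of paired stage labels (rows = system A)."""

    counts: np.ndarray
    row_labels: tuple = STAGE_LABELS
    col_labels: tuple = STAGE_LABELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.ndim != 2 or counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError(f"counts shape {counts.shape} does not match labels")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_text(self, name_a: str = "A", name_b: str = "B") -> str:
        width = max(5, *(len(l) for l in self.col_labels))
        head = " " * 8 + " ".join(f"{l:>{width}}" for l in self.col_labels) + "  total"
        lines = [f"{name_a} (rows) vs {name_b} (columns)", head]
        for label, row in zip(self.row_labels, self.counts):
            cells = " ".join(f"{c:>{width}}" for c in row)
            lines.append(f"{label:>7} {cells} {row.sum():>6}")
        cells = " ".join(f"{c:>{width}}" for c in self.col_marginals)
        lines.append(f"{'total':>7} {cells} {self.total:>6}")
        return "\n".join(lines)


def build_crosstab(
    stages_a: Sequence[str],
    stages_b: Sequence[str],
    labels: Sequence[str] = STAGE_LABELS,
) -> CrossTab:
    """Cross-tabulate paired stage labels; cell (i, j) counts A=i, B=j."""
    if len(stages_a) != len(stages_b):
        raise ValueError("paired label sequences differ in length")
    index = {label: i for i, label in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for a, b in zip(stages_a, stages_b):
        a, b = str(a), str(b)
        if a not in index or b not in index:
            raise ValueError(f"stage label outside {tuple(labels)}: ({a!r}, {b!r})")
        counts[index[a], index[b]] += 1
    return CrossTab(counts, tuple(labels), tuple(labels))


def percent_agreement(ct: CrossTab) -> float:
    """Diagonal mass as a percentage of the cohort."""
    if ct.total == 0:
        raise ValueError("empty cross-tabulation")
    return 100.0 * float(np.trace(ct.counts)) / ct.total


@dataclass(frozen=True)
class ShiftSummary:
    """Stage shifts of system A relative to system B, per B-stage and overall.

    Percentages use the B-stage column total as denominator; a patient is
    "downstaged" when A assigns a lower stage than B.
    """

    per_b_stage: dict  # label -> {'n': int, 'down': int, 'same': int, 'up': int}
    overall: dict

    def to_text(self) -> str:
        def fmt(name, d):
            if d["n"] == 0:
                return f"{name:>8}: n=0"
            parts = ", ".join(
                f"{k} {d[k]} ({100 * d[k] / d['n']:.2f}%)" for k in ("down", "same", "up")
            )
            return f"{name:>8}: n={d['n']}, {parts}"

        lines = [fmt(label, d) for label, d in self.per_b_stage.items()]
        lines.append(fmt("overall", self.overall))
        return "\n".join(lines)


def shift_summary(ct: CrossTab) -> ShiftSummary:
    """Count up/same/down stage shifts of the row system against the columns."""
    if ct.total == 0:
        raise ValueError("empty cross-tabulation")
    per: dict = {}
    overall = {"n": ct.total, "down": 0, "same": 0, "up": 0}
    for j, label in enumerate(ct.col_labels):
        col = ct.counts[:, j]
        d = {
            "n": int(col.sum()),
            "down": int(col[:j].sum()),
            "same": int(col[j]),
            "up": int(col[j + 1 :].sum()),
        }
        per[label] = d
        for k in ("down", "same", "up"):
            overall[k] += d[k]
    return ShiftSummary(per, overall)


def kappa_weight_matrix(k: int, scheme: str = "linear") -> np.ndarray:
    """Agreement-weight matrix in [0, 1]; 1 on the diagonal."""
    i, j = np.indices((k, k))
    if scheme == "linear":
        return 1.0 - np.abs(i - j) / (k - 1)
    if scheme == "quadratic":
        return 1.0 - ((i - j) / (k - 1)) ** 2
    if scheme == "unweighted":
        return (i == j).astype(float)
    raise ValueError(f"unknown weight scheme {scheme!r}")


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    po: float  # observed weighted agreement
    pe: float  # expected weighted agreement under marginal independence
    weight_matrix: np.ndarray
    standard_error: float  # non-null SE (for the CI)
    standard_error_null: float  # SE under H0 kappa = 0 (for the p-value)
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    scheme: str

    def to_text(self) -> str:
        return (
            f"{self.scheme}-weighted kappa = {self.kappa:.2f} "
            f"(95% CI, {self.ci_low:.2f} to {self.ci_high:.2f}; "
            f"p = {self.p_value:.3f}; n = {self.n})"
        )


def weighted_kappa(ct: CrossTab, scheme: str = "linear") -> KappaResult:
    """Cohen's weighted kappa with Fleiss-Cohen-Everitt asymptotic errors."""
    n = ct.total
    if n == 0:
        raise ValueError("empty cross-tabulation")
    k = ct.counts.shape[0]
    w = kappa_weight_matrix(k, scheme)
    p = ct.counts / n
    r = p.sum(axis=1)  # row marginals p_i.
    c = p.sum(axis=0)  # column marginals p_.j
    po = float((w * p).sum())
    pe = float((w * np.outer(r, c)).sum())
    if pe >= 1.0 - 1e-12:
        raise ValueError(
            "degenerate marginals: expected agreement is 1, kappa undefined "
            "(all mass in one category)"
        )
    kappa = (po - pe) / (1.0 - pe)

    # row/column weighted-marginal averages
    wbar_row = w @ c  # wbar_i. = sum_j c_j w_ij
    wbar_col = r @ w  # wbar_.j = sum_i r_i w_ij
    wsum = wbar_row[:, None] + wbar_col[None, :]

    # non-null variance (Fleiss, Cohen & Everitt 1969)
    term = (w * (1.0 - pe) - wsum * (1.0 - po)) ** 2
    var = ((p * term).sum() - (po * pe - 2.0 * pe + po) ** 2) / (n * (1.0 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    # variance under H0: kappa = 0
    var0 = (((np.outer(r, c)) * (w - wsum) ** 2).sum() - pe**2) / (n * (1.0 - pe) ** 2)
    se0 = float(np.sqrt(max(var0, 0.0)))

    z = 1.959963984540054
    ci_low, ci_high = kappa - z * se, kappa + z * se
    if se0 > 0:
        p_value = float(2.0 * sps.norm.sf(abs(kappa) / se0))
    else:
        p_value = float("nan") if kappa == 0 else 0.0
    return KappaResult(
        kappa=float(kappa),
        po=po,
        pe=pe,
        weight_matrix=w,
        standard_error=se,
        standard_error_null=se0,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p_value,
        n=n,
        scheme=scheme,
    )
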