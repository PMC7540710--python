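"""Good-practice accuracy assessment and area estimation.

Implements the stratified error-matrix estimators for thematic map
accuracy: with validation samples drawn within map strata, the cell
proportions are estimated as

    p_ij = W_i * n_ij / n_i.

where W_i is the mapped area proportion of stratum i. From these,
overall accuracy OA = sum_j p_jj, user's accuracy UA_i = p_ii / p_i.,
producer's accuracy PA_j = p_jj / p_.j, and the reference-corrected
class area A_j = A_total * p_.j, each with its variance estimator and a
95% confidence interval (z = 1.96). Raw count-based accuracies are also
exposed, since published per-class figures are often count-based.

Sampling within the mapped loss extent means loss omission error is
outside the design and is not estimated here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z95 = 1.96


@dataclass
class ErrorMatrix:
    """Cross-tabulation of map (rows) vs reference (columns) labels."""

    classes: list[str]
    counts: np.ndarray       # (k, k) int, n_ij
    map_areas: np.ndarray    # A_i, any consistent area unit

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.map_areas = np.asarray(self.map_areas, float)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if (self.map_areas < 0).any() or self.map_areas.sum() <= 0:
            raise ValueError("map areas must be non-negative with positive total")
        # a class absent from the map (zero area) is reference-only: it may
        # appear as a column but cannot have sampled rows
        empty_ok = self.map_areas == 0
        if (self.counts.sum(axis=1)[empty_ok] != 0).any():
            raise ValueError("zero-area map class cannot have samples")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def weights(self) -> np.ndarray:
        """Mapped area proportions W_i."""
        return self.map_areas / self.map_areas.sum()

    @property
    def sampled(self) -> np.ndarray:
        """Mask of map classes that exist in the map (positive area)."""
        return self.map_areas > 0

    @property
    def proportions(self) -> np.ndarray:
        """Estimated cell proportions p_ij = W_i n_ij / n_i.

        Rows for reference-only classes (zero area, no samples) are zero.
        """
        ni = self.row_totals
        if ((ni == 0) & self.sampled).any():
            bad = self.classes[int(np.argmin(np.where(self.sampled, ni, 1)))]
            raise ValueError(f"map class {bad!r} has no validation samples")
        safe_ni = np.maximum(ni, 1)
        return self.weights[:, None] * self.counts / safe_ni[:, None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass
class AccuracyReport:
    classes: list[str]
    overall: float
    overall_se: float
    users: np.ndarray
    users_se: np.ndarray
    producers: np.ndarray
    producers_se: np.ndarray
    users_counts: np.ndarray      # raw count-based UA, for comparison
    producers_counts: np.ndarray  # raw count-based PA

    def ci(self, estimate, se):
        lo = np.clip(np.asarray(estimate) - Z95 * np.asarray(se), 0.0, 1.0)
        hi = np.clip(np.asarray(estimate) + Z95 * np.asarray(se), 0.0, 1.0)
        return lo, hi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.classes,
            "users_accuracy": self.users,
            "users_se": self.users_se,
            "producers_accuracy": self.producers,
            "producers_se": self.producers_se,
            "users_accuracy_counts": self.users_counts,
            "producers_accuracy_counts": self.producers_counts,
        })


@dataclass
class AreaEstimate:
    classes: list[str]
    areas: np.ndarray         # reference-corrected A_j
    se: np.ndarray            # standard error in area units
    ci_halfwidth: np.ndarray  # 1.96 * se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.classes,
            "corrected_area": self.areas,
            "se": self.se,
            "ci95_halfwidth": self.ci_halfwidth,
        })


def allocate_samples(class_areas: dict[str, float], n_total: int) -> dict[str, int]:
    """Proportional sample allocation by largest-remainder rounding.

    Every class receives at least one sample; counts sum to ``n_total``.
    """
    names = list(class_areas)
    areas = np.array([class_areas[c] for c in names], float)
    if (areas <= 0).any() or not np.isfinite(areas).all():
        raise ValueError("class areas must be positive and finite")
    if n_total < len(names):
        raise ValueError("n_total smaller than the number of classes")
    quota = n_total * areas / areas.sum()
    counts = np.floor(quota).astype(int)
    counts = np.maximum(counts, 1)
    remainder = quota - np.floor(quota)
    # assign leftover samples to the largest remainders; deterministic ties
    order = np.argsort(-remainder, kind="stable")
    i = 0
    while counts.sum() < n_total:
        counts[order[i % len(names)]] += 1
        i += 1
    while counts.sum() > n_total:  # floors of 1 can overshoot
        j = int(np.argmax(counts))
        if counts[j] <= 1:
            raise ValueError("cannot allocate: too many classes at the floor")
        counts[j] -= 1
    return dict(zip(names, counts.tolist()))


def build_error_matrix(map_labels, reference_labels, map_areas: dict[str, float],
                       classes: list[str] | None = None) -> ErrorMatrix:
    """Cross-tabulate paired map/reference labels with mapped areas."""
    map_labels = np.asarray(map_labels)
    reference_labels = np.asarray(reference_labels)
    if map_labels.shape != reference_labels.shape:
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = sorted(map_areas)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), int)
    for m, r in zip(map_labels, reference_labels):
        if m not in idx or r not in idx:
            raise ValueError(f"label outside the class set: {m!r}/{r!r}")
        counts[idx[m], idx[r]] += 1
    areas = np.array([map_areas[c] for c in classes], float)
    return ErrorMatrix(list(classes), counts, areas)


def accuracy_report(matrix: ErrorMatrix) -> AccuracyReport:
    """OA/UA/PA with variance estimators from the stratified design."""
    p = matrix.proportions
    w = matrix.weights
    ni = matrix.row_totals.astype(float)
    counts = matrix.counts.astype(float)
    sampled = matrix.sampled

    overall = float(np.trace(p))
    with np.errstate(invalid="ignore", divide="ignore"):
        users = np.where(sampled, np.diag(p) / p.sum(axis=1), np.nan)
        col_p = p.sum(axis=0)
        producers = np.where(col_p > 0, np.diag(p) / col_p, np.nan)

    # variance estimators for stratified sampling (sampled strata only)
    users_var = np.full(len(ni), np.nan)
    users_var[sampled] = (users[sampled] * (1 - users[sampled])
                          / (ni[sampled] - 1))
    overall_var = float(np.sum(
        w[sampled] ** 2 * users[sampled] * (1 - users[sampled])
        / (ni[sampled] - 1)))

    # producer's accuracy variance: totals expressed in mapped-area units
    N = matrix.map_areas
    safe_ni = np.maximum(ni, 1)
    Nhat = (N[:, None] * counts / safe_ni[:, None]).sum(axis=0)
    k = len(matrix.classes)
    producers_var = np.full(k, np.nan)
    for j in range(k):
        if Nhat[j] == 0:
            continue
        term1 = 0.0
        if sampled[j]:
            term1 = (N[j] ** 2 * (1 - producers[j]) ** 2
                     * users[j] * (1 - users[j]) / (ni[j] - 1))
        term2 = 0.0
        for i in range(k):
            if i == j or not sampled[i]:
                continue
            pij = counts[i, j] / ni[i]
            term2 += N[i] ** 2 * pij * (1 - pij) / (ni[i] - 1)
        pa_j = producers[j] if np.isfinite(producers[j]) else 0.0
        producers_var[j] = (term1 + pa_j ** 2 * term2) / Nhat[j] ** 2

    with np.errstate(invalid="ignore", divide="ignore"):
        ua_counts = np.where(ni > 0, np.diag(counts) / ni, np.nan)
        colsum = counts.sum(axis=0)
        pa_counts = np.where(colsum > 0, np.diag(counts) / colsum, np.nan)

    return AccuracyReport(
        classes=list(matrix.classes),
        overall=overall, overall_se=float(np.sqrt(overall_var)),
        users=users, users_se=np.sqrt(users_var),
        producers=producers, producers_se=np.sqrt(producers_var),
        users_counts=ua_counts, producers_counts=pa_counts,
    )


def corrected_areas(matrix: ErrorMatrix) -> AreaEstimate:
    """Reference-corrected class areas with standard errors.

    A_j = A_total * sum_i W_i n_ij / n_i ;
    SE(p_.j) = sqrt( sum_i W_i^2 (n_ij/n_i)(1 - n_ij/n_i)/(n_i - 1) ).
    Corrected areas conserve the total mapped area.
    """
    ni = matrix.row_totals.astype(float)
    sampled = matrix.sampled
    if ((ni <= 1) & sampled).any():
        bad = matrix.classes[int(np.argmin(np.where(sampled, ni, 2)))]
        raise ValueError(
            f"map class {bad!r} has <= 1 sample; variance undefined")
    w = matrix.weights
    safe_ni = np.maximum(ni, 2)[:, None]
    frac = matrix.counts / safe_ni
    a_total = matrix.map_areas.sum()
    p_col = (w[:, None] * frac).sum(axis=0)
    se_p = np.sqrt(((w[:, None] ** 2) * frac * (1 - frac)
                    / (safe_ni - 1)).sum(axis=0))
    return AreaEstimate(list(matrix.classes), a_total * p_col,
                        a_total * se_p, Z95 * a_total * se_p)


def simulate_reference_labels(map_labels, confusion: np.ndarray,
                              classes: list[str],
                              rng: np.random.Generator):
    """Draw reference labels from a known per-map-class confusion model.

    ``confusion[i, j]`` is P(reference = class j | map = class i); rows
    must sum to one. Used for CI-coverage experiments.
    """
    confusion = np.asarray(confusion, float)
    if not np.allclose(confusion.sum(axis=1), 1.0):
        raise ValueError("confusion rows must sum to 1")
    idx = {c: i for i, c in enumerate(classes)}
    out = []
    for m in np.asarray(map_labels):
        out.append(classes[rng.choice(len(classes), p=confusion[idx[m]])])
    return np.array(out)
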