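"""Localization-ROC study assembly, synthetic observer, and AUC estimation.

Observer responses carry a 4-level confidence rating plus a marked location;
a lesion-present trial only counts toward detection if the mark falls within
the localization radius of the true center.  The localization-corrected AUC
is the Wilcoxon rank-sum statistic over (present, absent) rating pairs with
mislocalized present trials scored as misses.

Human readers are replaced by a parametric synthetic observer: a latent
Gaussian decision variable with mean equal to the detectability on
lesion-present trials, thresholded into ratings at fixed quartile cuts of
the null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tomotex.errors import DegenerateInputError, InventoryError, ParameterError

#: Rating cut points on the latent decision axis: the 50/90/99% quantiles of
#: the null.  High-confidence ratings are rare on lesion-absent trials, so a
#: strong observer can approach AUC = 1 despite the 4-level scale (symmetric
#: quartile cuts would cap the rating-based Wilcoxon statistic at 0.875).
RATING_CUTS = tuple(stats.norm.ppf([0.50, 0.90, 0.99]))

#: Default localization radius in pixels.
LOCALIZATION_RADIUS_PX = 15.0


@dataclass
class TrialRecord:
    image_id: str
    truth_present: bool
    rating: int
    true_center: Optional[tuple] = None  # (row, col), present trials only
    marked_location: Optional[tuple] = None
    condition: str = ""

    def __post_init__(self):
        if self.rating not in (1, 2, 3, 4):
            raise ParameterError(f"rating must be in 1..4; got {self.rating}")


@dataclass
class StudyResult:
    condition: str
    auc: float
    n_present: int
    n_absent: int
    correct_localization_fraction: float


def score_localization(marked: tuple, true_center: tuple, radius: float = LOCALIZATION_RADIUS_PX) -> bool:
    """Correct iff the Euclidean mark-to-center distance is <= ``radius``."""
    if marked is None or true_center is None:
        raise ParameterError("both the mark and the true center are required")
    d = np.hypot(marked[0] - true_center[0], marked[1] - true_center[1])
    return bool(d <= radius)


def _localization_flags(trials: Sequence[TrialRecord], radius: float) -> np.ndarray:
    flags = []
    for t in trials:
        if t.marked_location is None or t.true_center is None:
            flags.append(False)
        else:
            flags.append(score_localization(t.marked_location, t.true_center, radius))
    return np.asarray(flags, dtype=bool)


def lroc_auc(
    trials: Sequence[TrialRecord],
    radius: float = LOCALIZATION_RADIUS_PX,
    condition: str = "",
) -> StudyResult:
    """Localization-corrected Wilcoxon AUC.

    AUC = (1 / (Np * Na)) * sum over present/absent pairs of
    c_p * [ I(r_p > r_a) + 1/2 * I(r_p = r_a) ], with c_p = 1 iff the present
    trial is correctly localized.  Equivalent to exhaustive pair counting.
    """
    present = [t for t in trials if t.truth_present]
    absent = [t for t in trials if not t.truth_present]
    if not present or not absent:
        raise DegenerateInputError("need at least one present and one absent trial")
    r_p = np.array([t.rating for t in present], dtype=float)
    r_a = np.array([t.rating for t in absent], dtype=float)
    c_p = _localization_flags(present, radius)

    gt = (r_p[:, None] > r_a[None, :]).sum(axis=1)
    eq = (r_p[:, None] == r_a[None, :]).sum(axis=1)
    score = c_p * (gt + 0.5 * eq)
    auc = float(score.sum() / (len(r_p) * len(r_a)))
    return StudyResult(
        condition=condition or (present[0].condition if present else ""),
        auc=auc,
        n_present=len(present),
        n_absent=len(absent),
        correct_localization_fraction=float(c_p.mean()),
    )


def build_sessions(
    manifest: pd.DataFrame, n_train: int = 18, n_test: int = 54, seed: int = 0
) -> dict:
    """Seeded split of a condition's image manifest into training/test lists.

    Returns {"train": DataFrame, "test": DataFrame}; the two are disjoint.
    """
    total = n_train + n_test
    if len(manifest) < total:
        raise InventoryError(
            f"manifest has {len(manifest)} images; session needs {total}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(manifest))
    shuffled = manifest.iloc[order].reset_index(drop=True)
    train = shuffled.iloc[:n_train].reset_index(drop=True)
    test = shuffled.iloc[n_train : n_train + n_test].reset_index(drop=True)
    return {"train": train, "test": test}


def simulate_observer(
    session: pd.DataFrame,
    detectability: float,
    loc_error_scale: float,
    guess_area: np.ndarray,
    seed: int = 0,
    perception_threshold: float = 0.0,
    condition: str = "",
) -> list:
    """Parametric observer: latent ~ Normal(detectability * truth, 1).

    Ratings come from fixed quartile cuts of the null.  A present trial whose
    latent score clears ``perception_threshold`` marks near the true center
    (isotropic Gaussian error of scale ``loc_error_scale``); otherwise, and on
    absent trials, the mark is uniform over ``guess_area`` (a boolean mask).

    ``session`` rows need: image_id, truth_present, truth_row, truth_col.
    """
    if not np.isfinite(detectability):
        raise ParameterError("detectability must be finite")
    if loc_error_scale < 0:
        raise ParameterError("loc_error_scale must be nonnegative")
    guess_area = np.asarray(guess_area, dtype=bool)
    guess_pixels = np.argwhere(guess_area)
    if len(guess_pixels) == 0:
        raise ParameterError("guess_area must contain at least one pixel")

    rng = np.random.default_rng(seed)
    # All randomness is drawn up front, independent of branch outcomes, so
    # that a fixed seed gives common random numbers across detectability
    # levels (AUC is then monotone in detectability by construction).
    n = len(session)
    latent_noise = rng.normal(0.0, 1.0, size=n)
    loc_noise = rng.normal(0.0, 1.0, size=(n, 2))
    guess_idx = rng.integers(len(guess_pixels), size=n)

    trials = []
    for k, (_, row) in enumerate(session.iterrows()):
        present = bool(row["truth_present"])
        latent = latent_noise[k] + (detectability if present else 0.0)
        rating = 1 + int(np.searchsorted(RATING_CUTS, latent))
        true_center = None
        if present:
            true_center = (float(row["truth_row"]), float(row["truth_col"]))
        mark = None
        if present and latent >= perception_threshold:
            cand = (
                true_center[0] + loc_error_scale * loc_noise[k, 0],
                true_center[1] + loc_error_scale * loc_noise[k, 1],
            )
            r, c = int(round(cand[0])), int(round(cand[1]))
            inside = 0 <= r < guess_area.shape[0] and 0 <= c < guess_area.shape[1]
            if inside and guess_area[r, c]:
                mark = cand
        if mark is None:
            # absent, missed, or a perceived mark that fell off the image:
            # the observer guesses uniformly over the searchable area
            gr, gc = guess_pixels[guess_idx[k]]
            mark = (float(gr), float(gc))
        trials.append(
            TrialRecord(
                image_id=str(row["image_id"]),
                truth_present=present,
                rating=rating,
                true_center=true_center,
                marked_location=mark,
                condition=condition,
            )
        )
    return trials


def auc_vs_detectability(
    session: pd.DataFrame,
    detectabilities: Sequence[float],
    loc_error_scale: float,
    guess_area: np.ndarray,
    seed: int = 0,
    n_reps: int = 1,
) -> np.ndarray:
    """Mean simulated AUC at each detectability, with common random numbers."""
    out = np.zeros(len(detectabilities))
    for k, d in enumerate(detectabilities):
        aucs = [
            lroc_auc(simulate_observer(session, d, loc_error_scale, guess_area, seed=seed + rep)).auc
            for rep in range(n_reps)
        ]
        out[k] = float(np.mean(aucs))
    return out


def fit_detectability(
    observed_auc: float,
    session: pd.DataFrame,
    loc_error_scale: float,
    guess_area: np.ndarray,
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
    n_reps: int = 4,
) -> float:
    """Invert the (monotone) AUC-detectability curve by grid interpolation."""
    if grid is None:
        grid = np.linspace(0.0, 6.0, 25)
    curve = auc_vs_detectability(session, grid, loc_error_scale, guess_area, seed=seed, n_reps=n_reps)
    # Enforce monotonicity for a stable inverse.
    curve = np.maximum.accumulate(curve)
    return float(np.interp(observed_auc, curve, grid))


def trials_to_frame(trials: Sequence[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "image_id": t.image_id,
                "truth_present": t.truth_present,
                "rating": t.rating,
                "truth_row": None if t.true_center is None else t.true_center[0],
                "truth_col": None if t.true_center is None else t.true_center[1],
                "marked_row": None if t.marked_location is None else t.marked_location[0],
                "marked_col": None if t.marked_location is None else t.marked_location[1],
                "condition": t.condition,
            }
        )
    return pd.DataFrame(rows)


def trials_from_frame(df: pd.DataFrame) -> list:
    trials = []
    for _, r in df.iterrows():
        center = None
        if pd.notna(r.get("truth_row")) and pd.notna(r.get("truth_col")):
            center = (float(r["truth_row"]), float(r["truth_col"]))
        mark = None
        if pd.notna(r.get("marked_row")) and pd.notna(r.get("marked_col")):
            mark = (float(r["marked_row"]), float(r["marked_col"]))
        trials.append(
            TrialRecord(
                image_id=str(r["image_id"]),
                truth_present=bool(r["truth_present"]),
                rating=int(r["rating"]),
                true_center=center,
                marked_location=mark,
                condition=str(r.get("condition", "")),
            )
        )
    return trials
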