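"""Bliss-excess synergy surfaces for two-drug dose checkerboards.

Raw replicate responses are converted to fraction affected
E(i,j) = 1 − response(i,j)/response(0,0), the Bliss-expected combination
effect is built from the grid's own single-agent row and column,
E_exp(i,j) = E_a(i) + E_b(j) − E_a(i)·E_b(j), and the synergy surface is
the excess E_obs − E_exp.  Positive excess = synergy (the sign convention
is stamped on every output header).  Replicates give a per-cell SD and,
with n ≥ 3, a one-sample t test of excess ≠ 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateReferenceError, DomainError
from .screen_data import CheckerboardGrid

SIGN_CONVENTION = "positive excess = synergy (observed effect exceeds Bliss expectation)"


@dataclass
class SynergySurface:
    """Observed / expected / excess effect matrices over a dose grid."""

    drug_a_doses: np.ndarray
    drug_b_doses: np.ndarray
    observed_effect: np.ndarray
    expected_effect: np.ndarray
    excess: np.ndarray
    per_cell_sd: np.ndarray | None = None
    p_values: np.ndarray | None = None
    n_reps: int = 1
    observed_raw: np.ndarray | None = None  # unclamped, for audit
    summary_score: float = field(init=False)

    def __post_init__(self):
        shapes = {self.observed_effect.shape, self.expected_effect.shape, self.excess.shape}
        if len(shapes) != 1:
            raise ValueError("surface matrices must share dimensions")
        combo = np.ix_(
            np.arange(len(self.drug_a_doses)) > 0, np.arange(len(self.drug_b_doses)) > 0
        )
        self.summary_score = float(np.mean(self.excess[combo])) if self.excess[combo].size else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (dose_a, dose_b) cell."""
        ai, bi = np.meshgrid(
            np.arange(len(self.drug_a_doses)), np.arange(len(self.drug_b_doses)), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "dose_a": self.drug_a_doses[ai.ravel()],
                "dose_b": self.drug_b_doses[bi.ravel()],
                "observed": self.observed_effect.ravel(),
                "expected": self.expected_effect.ravel(),
                "excess": self.excess.ravel(),
                "sd": (self.per_cell_sd.ravel() if self.per_cell_sd is not None else np.nan),
                "p_value": (self.p_values.ravel() if self.p_values is not None else np.nan),
                "n": self.n_reps,
            }
        )
        if self.observed_raw is not None:
            df["observed_raw"] = self.observed_raw.ravel()
        return df


def _fraction_affected_one(responses: np.ndarray, clamp: bool = True) -> np.ndarray:
    anchor = responses[0, 0]
    if anchor <= 0:
        raise DegenerateReferenceError("untreated (0,0) anchor response must be > 0")
    e = 1.0 - responses / anchor
    return np.clip(e, 0.0, 1.0) if clamp else e


def to_fraction_affected(grid: CheckerboardGrid, clamp: bool = True) -> np.ndarray:
    """Mean fractional inhibition matrix, anchored to the (0,0) cell.

    E(i,j) = 1 − mean_response(i,j)/mean_response(0,0), clamped to [0,1]
    (unclamped with ``clamp=False`` for audit).  E(0,0) is 0 by
    construction; growth beyond untreated clamps to 0.
    """
    return _fraction_affected_one(grid.responses.mean(axis=0), clamp=clamp)


def bliss_expected(e_a: np.ndarray, e_b: np.ndarray) -> np.ndarray:
    """Bliss-independent expected effect E_a + E_b − E_a·E_b as a matrix."""
    e_a = np.asarray(e_a, dtype=float)
    e_b = np.asarray(e_b, dtype=float)
    if np.any((e_a < 0) | (e_a > 1)) or np.any((e_b < 0) | (e_b > 1)):
        raise DomainError("single-agent effects must lie in [0, 1]")
    return e_a[:, None] + e_b[None, :] - np.outer(e_a, e_b)


def bliss_excess(
    observed: np.ndarray,
    expected: np.ndarray,
    drug_a_doses: np.ndarray,
    drug_b_doses: np.ndarray,
    per_cell_sd: np.ndarray | None = None,
    n_reps: int = 1,
    replicate_excess: np.ndarray | None = None,
    observed_raw: np.ndarray | None = None,
) -> SynergySurface:
    """Assemble the synergy surface from observed and expected effects.

    Excess = observed − expected (positive = synergy).  With fewer than two
    replicates the uncertainty is omitted with a warning; with ``n_reps >=
    3`` and per-replicate excess matrices supplied, a per-cell one-sample t
    test of excess ≠ 0 is reported.
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must share dimensions")
    excess = observed - expected
    p_values = None
    if n_reps < 2:
        warnings.warn("fewer than 2 replicates: per-cell uncertainty omitted", stacklevel=2)
        per_cell_sd = None
    elif n_reps >= 3 and replicate_excess is not None:
        with np.errstate(invalid="ignore", divide="ignore"):
            p_values = stats.ttest_1samp(replicate_excess, 0.0, axis=0).pvalue
    return SynergySurface(
        drug_a_doses=np.asarray(drug_a_doses, dtype=float),
        drug_b_doses=np.asarray(drug_b_doses, dtype=float),
        observed_effect=observed,
        expected_effect=expected,
        excess=excess,
        per_cell_sd=per_cell_sd,
        p_values=p_values,
        n_reps=n_reps,
        observed_raw=observed_raw,
    )


def analyze_checkerboard(grid: CheckerboardGrid) -> SynergySurface:
    """Full pipeline: grid → fraction affected → Bliss expectation → excess.

    Single-agent effect vectors are the grid's own first column (drug A
    alone) and first row (drug B alone); no dose-response refitting.  The
    mean surface uses mean responses; the per-cell SD and t test come from
    per-replicate excess surfaces (each replicate anchored and Bliss-
    expected from its own axes).
    """
    observed = to_fraction_affected(grid)
    observed_raw = to_fraction_affected(grid, clamp=False)
    expected = bliss_expected(observed[:, 0], observed[0, :])

    per_cell_sd = None
    replicate_excess = None
    if grid.n_reps >= 2:
        rep_excess = []
        for rep in range(grid.n_reps):
            e = _fraction_affected_one(grid.responses[rep])
            rep_excess.append(e - bliss_expected(e[:, 0], e[0, :]))
        replicate_excess = np.stack(rep_excess)
        per_cell_sd = replicate_excess.std(axis=0, ddof=1)
    return bliss_excess(
        observed,
        expected,
        grid.drug_a_doses,
        grid.drug_b_doses,
        per_cell_sd=per_cell_sd,
        n_reps=grid.n_reps,
        replicate_excess=replicate_excess,
        observed_raw=observed_raw,
    )


def plot_surface(surface: SynergySurface, path) -> None:
    """Heat map of the excess matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    vmax = max(0.2, float(np.abs(surface.excess).max()))
    im = ax.imshow(
        surface.excess, origin="lower", cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto"
    )
    ax.set_xticks(range(len(surface.drug_b_doses)), [f"{d:g}" for d in surface.drug_b_doses])
    ax.set_yticks(range(len(surface.drug_a_doses)), [f"{d:g}" for d in surface.drug_a_doses])
    ax.set_xlabel("drug B dose")
    ax.set_ylabel("drug A dose")
    ax.set_title(f"Bliss excess (summary {surface.summary_score:+.3f})")
    fig.colorbar(im, ax=ax, label="excess over Bliss")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
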