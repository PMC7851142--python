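"""Synthetic combination screens, checkerboards and dose-response series.

The generative model is deliberately the minimal one under which the
pipeline's statistics have closed-form truth: a well's expected count is

    N0 · plate_scale · g(gene) · b[drug arm] · s(gene)[siRNA+drug only]

with g the knockdown (gene-effect) multiplier, b the drug effect on
control cells, and s the planted gene x drug interaction multiplier
(s < 1 synergy, 1 none, > 1 antagonism).  Because every factor is
multiplicative, the noiseless pipeline recovers CDI == s and
Δ == g·(1 − b·s) exactly — the identity every recovery test leans on.
Well noise is multiplicative log-normal with unit mean and a given CV
(counts are positive and right-skewed); noisy counts are rounded to
integers, noiseless ones are left as exact expectations.

Duplexes realise a ``penetrance`` fraction p of the pooled effect:
multiplier 1 − p·(1−g), interaction 1 − p·(1−s).  The default ladder
{1.0, 0.9, 0.5, 0.2} makes some duplexes of a true-synergy gene fail the
secondary criteria, exercising the 2-of-4 concordance rule realistically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .screen_data import ScreenDesign, WellRecord

N_CONTROL_WELLS = 16
PLATE_CAPACITY = 384


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


@dataclass
class SimTruth:
    """Ground truth of a simulated screen, keyed by gene / duplex / plate.

    ``gene_effects`` maps gene -> knockdown survival multiplier g in (0, 1.2];
    ``drug_effect`` is the control-cell survival multiplier b under drug;
    ``interaction`` maps gene -> s applied only in the siRNA+drug condition
    (expected CDI equals s in the noiseless limit).  ``duplex_penetrance``
    is the fraction of the pooled effect each of the four duplexes realises.
    """

    gene_effects: dict[str, float]
    drug_effect: float = 0.6
    interaction: dict[str, float] = field(default_factory=dict)
    duplex_penetrance: tuple[float, ...] = (1.0, 0.9, 0.5, 0.2)
    noise_cv: float = 0.1
    plate_scale: dict[str, float] = field(default_factory=dict)
    baseline_count: float = 2000.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise DomainError("noise_cv must be >= 0")
        if not 0 < self.drug_effect <= 1:
            raise DomainError("drug_effect must lie in (0, 1]")
        for g, v in self.gene_effects.items():
            if not 0 < v <= 1.2:
                raise DomainError(f"gene effect for {g} must lie in (0, 1.2], got {v}")

    def interaction_of(self, gene: str) -> float:
        return self.interaction.get(gene, 1.0)

    @property
    def synergy_genes(self) -> set[str]:
        return {g for g, s in self.interaction.items() if s < 1}

    @classmethod
    def random(
        cls,
        n_genes: int,
        n_synergy: int = 0,
        s: float = 0.5,
        synergy_gene_effect: float = 0.8,
        gene_effect_range: tuple[float, float] = (0.5, 1.0),
        drug_effect: float = 0.6,
        noise_cv: float = 0.1,
        seed: int = 0,
    ) -> "SimTruth":
        """A screen of ``n_genes`` with the first ``n_synergy`` planted at s.

        Non-synergy genes draw their knockdown effect uniformly from
        ``gene_effect_range``; planted genes use ``synergy_gene_effect``.
        """
        if n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if n_synergy > n_genes:
            raise ValueError("n_synergy cannot exceed n_genes")
        rng = np.random.default_rng(seed)
        genes = [f"G{i+1:04d}" for i in range(n_genes)]
        effects = dict(
            zip(genes, rng.uniform(*gene_effect_range, size=n_genes).round(6))
        )
        interaction = {}
        for g in genes[:n_synergy]:
            effects[g] = synergy_gene_effect
            interaction[g] = s
        return cls(
            gene_effects=effects,
            drug_effect=drug_effect,
            interaction=interaction,
            noise_cv=noise_cv,
            seed=seed,
        )

    def truth_table(self) -> pd.DataFrame:
        rows = [
            (g, eff, self.drug_effect, self.interaction_of(g), self.interaction_of(g) < 1)
            for g, eff in sorted(self.gene_effects.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene_symbol", "gene_effect", "drug_effect", "interaction", "synergy"]
        )


def _well_positions(n: int) -> list[str]:
    rows = "ABCDEFGHIJKLMNOP"
    return [f"{rows[i // 24]}{i % 24 + 1:02d}" for i in range(n)]


def simulate_screen(
    n_genes: int | None,
    config: SimTruth,
    design: ScreenDesign | None = None,
    layout: str = "pool",
) -> tuple[list[WellRecord], SimTruth]:
    """Generate the wells of a two-arm replicate-plate screen plus its truth.

    ``layout="pool"`` emits one SMARTpool well per gene (primary screen);
    ``layout="duplex"`` emits ``design.duplexes_per_gene`` wells per gene
    (secondary deconvolution screen), each with its penetrance-attenuated
    effect.  Each plate carries 16 non-targeting control wells; genes
    overflow onto additional plate chunks when a plate fills.  Fully
    reproducible from ``config.seed``; plate scale factors default to 1 and
    are recorded back into the returned truth.
    """
    design = design or ScreenDesign()
    if n_genes is not None and n_genes != len(config.gene_effects):
        raise ValueError(
            f"n_genes={n_genes} disagrees with config ({len(config.gene_effects)} genes)"
        )
    if layout not in ("pool", "duplex"):
        raise ValueError("layout must be 'pool' or 'duplex'")
    genes = sorted(config.gene_effects)

    if layout == "pool":
        reagents = [(f"pool_{g}", g, "pool", 1.0) for g in genes]
    else:
        pen = config.duplex_penetrance[: design.duplexes_per_gene]
        reagents = [
            (f"dx{k+1}_{g}", g, "duplex", p)
            for g in genes
            for k, p in enumerate(pen)
        ]

    capacity = PLATE_CAPACITY - N_CONTROL_WELLS
    chunks = [reagents[i : i + capacity] for i in range(0, len(reagents), capacity)]
    control_id = sorted(design.control_reagent_ids)[0]

    rng = np.random.default_rng(config.seed)
    plate_scale = dict(config.plate_scale)
    wells: list[WellRecord] = []
    for arm in design.arms:
        is_drug = arm == design.drug_arm
        for rep in range(1, design.replicates_per_arm + 1):
            for ci, chunk in enumerate(chunks, start=1):
                plate_id = f"{layout}-{arm}-r{rep}-p{ci}"
                scale = plate_scale.setdefault(plate_id, 1.0)
                positions = _well_positions(N_CONTROL_WELLS + len(chunk))
                mult = [1.0] * N_CONTROL_WELLS
                meta = [(control_id, "", "nontargeting_control")] * N_CONTROL_WELLS
                for rid, gene, rclass, pen in chunk:
                    g = 1.0 - pen * (1.0 - config.gene_effects[gene])
                    m = g
                    if is_drug:
                        s = 1.0 - pen * (1.0 - config.interaction_of(gene))
                        m *= config.drug_effect * s
                    mult.append(m)
                    meta.append((rid, gene, rclass))
                expected = config.baseline_count * scale * np.asarray(mult)
                if is_drug:
                    expected[:N_CONTROL_WELLS] *= config.drug_effect
                counts = expected * _lognormal_noise(rng, config.noise_cv, len(expected))
                if config.noise_cv > 0:
                    counts = np.round(counts)
                for pos, (rid, gene, rclass), c in zip(positions, meta, counts):
                    wells.append(
                        WellRecord(
                            plate_id=plate_id,
                            well=pos,
                            reagent_id=rid,
                            gene_symbol=gene,
                            reagent_class=rclass,
                            treatment=arm,
                            cell_count=float(c),
                        )
                    )
    truth = replace(config, plate_scale=plate_scale)
    return wells, truth


def deviation_for_excess(excess: float, expected_survival: float) -> float:
    """Deviation term planting an exact Bliss excess at a cell.

    The simulator multiplies Bliss-independent survival by exp(−deviation);
    the excess it produces at a cell with expected survival S is
    S·(1 − exp(−dev)).  This inverts that relation.
    """
    if not 0 < expected_survival <= 1:
        raise DomainError("expected survival must lie in (0, 1]")
    if excess >= expected_survival:
        raise DomainError("cannot plant an excess at or beyond full kill")
    return -math.log(1.0 - excess / expected_survival)


def simulate_checkerboard(
    ec50_a: float,
    hill_a: float,
    ec50_b: float,
    hill_b: float,
    bliss_deviation: float | np.ndarray = 0.0,
    noise_cv: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
    doses_a: np.ndarray | None = None,
    doses_b: np.ndarray | None = None,
    baseline: float = 100.0,
):
    """Replicate checkerboard responses with a known excess-over-Bliss truth.

    Single-agent survivals follow 4PL curves S(d) = 1/(1 + (d/ec50)^hill);
    combined survival is the Bliss product scaled by exp(−deviation), so a
    positive deviation plants synergy.  Returns ``(CheckerboardGrid,
    truth_excess)`` where ``truth_excess`` is the exact expected excess
    surface (zero along the single-agent axes by construction).
    Default dose axes: 0 plus 5 doses geometrically spanning ec50/4..4·ec50.
    """
    from .screen_data import CheckerboardGrid  # local to avoid cycle at import time

    if ec50_a <= 0 or ec50_b <= 0:
        raise DomainError("EC50s must be positive")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    if doses_a is None:
        doses_a = np.concatenate(([0.0], ec50_a * np.geomspace(0.25, 4.0, 5)))
    if doses_b is None:
        doses_b = np.concatenate(([0.0], ec50_b * np.geomspace(0.25, 4.0, 5)))
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)

    def survival(d, ec50, hill):
        with np.errstate(divide="ignore"):
            x = np.where(d > 0, np.power(d / ec50, hill), 0.0)
        return 1.0 / (1.0 + x)

    s_a = survival(doses_a, ec50_a, hill_a)
    s_b = survival(doses_b, ec50_b, hill_b)
    s_bliss = np.outer(s_a, s_b)

    dev = np.broadcast_to(np.asarray(bliss_deviation, dtype=float), s_bliss.shape).copy()
    dev[0, :] = 0.0  # single agents define their own expectation: no
    dev[:, 0] = 0.0  # deviation along the axes
    s_combined = s_bliss * np.exp(-dev)
    truth_excess = s_bliss - s_combined

    rng = np.random.default_rng(seed)
    reps = np.stack(
        [
            baseline * s_combined * _lognormal_noise(rng, noise_cv, s_combined.shape)
            for _ in range(n_reps)
        ]
    )
    grid = CheckerboardGrid(drug_a_doses=doses_a, drug_b_doses=doses_b, responses=reps)
    return grid, truth_excess


def simulate_dose_response(
    ec50: float,
    hill: float = 1.0,
    lower: float = 0.0,
    upper: float = 1.0,
    n_doses: int = 8,
    n_reps: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
):
    """(doses, responses) from a known 4PL with multiplicative noise.

    Doses: 0 plus ``n_doses − 1`` points geometrically spanning
    ec50/16..16·ec50; each dose measured ``n_reps`` times.
    """
    from .dose_response import four_pl

    doses = np.concatenate(([0.0], ec50 * np.geomspace(1 / 16, 16, n_doses - 1)))
    doses = np.repeat(doses, n_reps)
    rng = np.random.default_rng(seed)
    resp = four_pl(doses, lower, upper, math.log(ec50), hill)
    resp = resp * _lognormal_noise(rng, noise_cv, resp.shape)
    return doses, resp


def evaluate_recovery(
    truth: SimTruth,
    primary_calls: pd.DataFrame | None = None,
    validated: pd.DataFrame | None = None,
) -> dict:
    """Precision / recall / FPR of hit calls against the planted synergies.

    ``primary_calls`` is a table from ``call_primary``; ``validated`` from
    ``concordance``.  Precision is NaN (undefined flag) when no calls were
    made or no synergy was planted and nothing was called.
    Raises on genes outside the truth's namespace.
    """
    results: dict = {}
    synergy = truth.synergy_genes
    all_genes = set(truth.gene_effects)

    def _score(called: set[str], stage: str):
        unknown = called - all_genes
        if unknown:
            raise ValueError(
                f"{stage} calls contain genes outside the truth namespace: "
                f"{', '.join(sorted(unknown))}"
            )
        tp = len(called & synergy)
        fp = len(called - synergy)
        fn = len(synergy - called)
        n_null = len(all_genes - synergy)
        results[f"{stage}_precision"] = tp / (tp + fp) if (tp + fp) else math.nan
        results[f"{stage}_recall"] = tp / (tp + fn) if synergy else math.nan
        results[f"{stage}_fpr"] = fp / n_null if n_null else math.nan
        results[f"{stage}_missed"] = fn

    if primary_calls is not None:
        _score(set(primary_calls.loc[primary_calls["passed"], "gene_symbol"]), "primary")
    if validated is not None:
        _score(set(validated.loc[validated["validated"], "gene_symbol"]), "validated")
    results["n_synergy_planted"] = len(synergy)
    results["n_genes"] = len(all_genes)
    return results
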