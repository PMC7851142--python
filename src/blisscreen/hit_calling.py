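"""Two-stage hit selection with duplex-deconvolution concordance.

Primary stage: a SMARTpool is a hit when Δ >= 0.25 and CDI <= 0.9 (both
bounds inclusive, exactly as printed in the screen's selection criteria).
Secondary stage: each of the four duplexes comprising a pool is re-scored
individually against tighter criteria (Δ >= 0.15, CDI <= 0.8), and a gene
is *validated* when at least ``min_concordant`` (default 2) of its duplexes
pass — concordance across independent sequences argues against off-target
artefacts.  Undefined CDI (zero denominator) never passes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import AmbiguityError

PRIMARY_DELTA_MIN = 0.25
PRIMARY_CDI_MAX = 0.9
DUPLEX_DELTA_MIN = 0.15
DUPLEX_CDI_MAX = 0.8
MIN_CONCORDANT = 2

HIT_COLUMNS = (
    "gene_symbol",
    "reagent_id",
    "stage",
    "delta",
    "cdi",
    "cdi_defined",
    "passed",
    "delta_min",
    "cdi_max",
)


def _call(scores: pd.DataFrame, stage: str, delta_min: float, cdi_max: float) -> pd.DataFrame:
    defined = scores["cdi"].notna() & np.isfinite(scores["cdi"].to_numpy(dtype=float))
    passed = (
        defined
        & (scores["delta"] >= delta_min)
        & (scores["cdi"] <= cdi_max)
    )
    out = pd.DataFrame(
        {
            "gene_symbol": scores["gene_symbol"],
            "reagent_id": scores["reagent_id"],
            "stage": stage,
            "delta": scores["delta"],
            "cdi": scores["cdi"],
            "cdi_defined": defined,
            "passed": passed,
            "delta_min": delta_min,
            "cdi_max": cdi_max,
        }
    )
    return out.sort_values(["gene_symbol", "reagent_id"], kind="stable").reset_index(
        drop=True
    )


def call_primary(
    scores: pd.DataFrame,
    delta_min: float = PRIMARY_DELTA_MIN,
    cdi_max: float = PRIMARY_CDI_MAX,
) -> pd.DataFrame:
    """Apply the primary SMARTpool criteria; one HitCall row per gene.

    ``scores`` is a GeneScore table restricted to pool-class reagents.
    Boundary values pass (>= and <= as printed); genes whose CDI is
    undefined get ``passed == False`` and ``cdi_defined == False`` so they
    can be listed separately.  Raises :class:`AmbiguityError` if a gene is
    represented by more than one pool reagent.
    """
    pools = scores[scores.get("reagent_class", "pool") == "pool"] if "reagent_class" in scores else scores
    dup = pools["gene_symbol"][pools["gene_symbol"].duplicated()]
    if not dup.empty:
        raise AmbiguityError(
            f"gene(s) with multiple pool reagents: {', '.join(sorted(set(dup)))}"
        )
    return _call(pools, "primary", delta_min, cdi_max)


def call_duplexes(
    scores: pd.DataFrame,
    delta_min: float = DUPLEX_DELTA_MIN,
    cdi_max: float = DUPLEX_CDI_MAX,
) -> pd.DataFrame:
    """Apply the secondary (deconvolution) criteria per individual duplex."""
    duplexes = (
        scores[scores["reagent_class"] == "duplex"] if "reagent_class" in scores else scores
    )
    return _call(duplexes, "duplex", delta_min, cdi_max)


def concordance(
    duplex_calls: pd.DataFrame, min_concordant: int = MIN_CONCORDANT
) -> pd.DataFrame:
    """Aggregate duplex calls per gene into the n-of-4 validation verdict.

    A gene is validated when the absolute count of passing duplexes reaches
    ``min_concordant`` (the rule is an absolute count, not a fraction, so
    genes with fewer than four recovered duplexes face the same bar).
    Output records both counts, formatted as e.g. "2/4".
    """
    if min_concordant < 1:
        raise ValueError("min_concordant must be >= 1")
    rows = []
    for gene, sub in duplex_calls.groupby("gene_symbol"):
        n_tested = len(sub)
        n_pass = int(sub["passed"].sum())
        rows.append((gene, n_tested, n_pass, n_pass >= min_concordant, f"{n_pass}/{n_tested}"))
    out = pd.DataFrame(
        rows,
        columns=["gene_symbol", "n_duplexes_tested", "n_duplexes_passing", "validated", "label"],
    )
    return out.sort_values("gene_symbol", kind="stable").reset_index(drop=True)
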