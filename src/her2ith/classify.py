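"""High- vs low-heterogeneity classification from fitted mixtures.

A tumor is *high heterogeneity* (HH, biphasic histogram) when the fitted
mixture reveals a genuine low-copy subpopulation inside an overall
HER2-amplified tumor; everything else is *low heterogeneity* (LH,
monophasic).  Concretely, HH requires all of:

1. model selection prefers two components (BIC, see ``gmm.select_components``);
2. the lower-mean component carries weight >= ``pi_min`` (default 0.10 — a
   subpopulation must be non-negligible);
3. the lower-mean component sits below ``tau_low`` copies (default 2.0,
   i.e. fewer than two HER2 copies per cell);
4. the overall mixture mean stays at or above ``tau_pos`` copies
   (default 2.0, the tumor remains HER2-amplified on average).

Every criterion's outcome is recorded in a decision trace, so a label is
always auditable.  Raising ``pi_min`` or lowering ``tau_low`` can only turn
HH labels into LH, never the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmm import FitOptions, ModelSelection, select_components
from .histogram import SignalHistogram, histogram_from_cells, summarize_tumor

__all__ = ["ITHOptions", "ITHResult", "CohortClassification",
           "classify_ith", "classify_cohort"]


@dataclass(frozen=True)
class ITHOptions:
    """Thresholds of the heterogeneity call (all in copy-number units
    except the dimensionless weight cutoff ``pi_min``)."""

    tau_low: float = 2.0
    tau_pos: float = 2.0
    pi_min: float = 0.10

    def __post_init__(self):
        if self.tau_low <= 0 or self.tau_pos <= 0:
            raise ValueError("tau_low and tau_pos must be positive")
        if not 0.0 < self.pi_min <= 0.5:
            raise ValueError("pi_min must lie in (0, 0.5]")


@dataclass(frozen=True)
class ITHResult:
    """The HH/LH label plus everything the decision used."""

    label: str  # "HH" | "LH"
    chosen_k: int
    overall_mean: float
    low_component: tuple[float, float, float] | None  # (pi, mu, sigma) if k=2
    decision_trace: dict[str, bool]
    selection: ModelSelection = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "chosen_k": self.chosen_k,
            "overall_mean": self.overall_mean,
            "decision_trace": dict(self.decision_trace),
        }
        if self.low_component is not None:
            pi, mu, sigma = self.low_component
            d["low_component"] = {"pi": pi, "mu": mu, "sigma": sigma}
        return d


def classify_ith(hist: SignalHistogram, fit_options: FitOptions | None = None,
                 ith_options: ITHOptions | None = None) -> ITHResult:
    """Classify one tumor's histogram as HH or LH."""
    ith = ith_options or ITHOptions()
    sel = select_components(hist, fit_options, pi_min=ith.pi_min)
    fit = sel.chosen
    overall_mean = fit.mixture_mean

    trace: dict[str, bool] = {"two_components": sel.chosen_k == 2}
    low = None
    if sel.chosen_k == 2:
        pi_low, mu_low, sd_low = (float(fit.weights[0]), float(fit.means[0]),
                                  float(fit.sds[0]))
        low = (pi_low, mu_low, sd_low)
        trace["subclone_weight"] = pi_low >= ith.pi_min
        trace["subclone_low_copy"] = mu_low < ith.tau_low
        trace["overall_amplified"] = overall_mean >= ith.tau_pos
    label = "HH" if all(trace.values()) and sel.chosen_k == 2 else "LH"
    return ITHResult(label=label, chosen_k=sel.chosen_k,
                     overall_mean=overall_mean, low_component=low,
                     decision_trace=trace, selection=sel)


@dataclass
class CohortClassification:
    """Per-tumor labels plus cohort-level summaries.

    ``table`` extends the input cohort table with ith_label, chosen_k,
    overall_mean, pi_low, mu_low and fish_ratio columns; ``prevalence`` is
    the recovered HH fraction; ``group_mean_fish_ratio`` maps label ->
    mean FISH ratio; ``excluded`` lists (tumor_id, reason) for tumors that
    could not be classified.
    """

    table: pd.DataFrame
    results: dict[str, ITHResult]
    prevalence: float
    group_mean_fish_ratio: dict[str, float]
    excluded: list[tuple[str, str]]

    @property
    def n_hh(self) -> int:
        return int((self.table["ith_label"] == "HH").sum())


def classify_cohort(cohort, fit_options: FitOptions | None = None,
                    ith_options: ITHOptions | None = None) -> CohortClassification:
    """Classify every tumor of a cohort and summarise prevalence.

    ``cohort`` is a :class:`~her2ith.synth.CohortTable` (or anything with a
    ``table`` DataFrame and a ``cells``/``histogram`` accessor).  Tumors
    without cells are excluded with a logged reason, never silently.
    """
    rows = []
    results: dict[str, ITHResult] = {}
    excluded: list[tuple[str, str]] = []
    for _, rec in cohort.table.iterrows():
        tid = rec["tumor_id"]
        try:
            cells = cohort.cells[tid]
        except KeyError:
            excluded.append((tid, "no cell counts available"))
            continue
        hist = histogram_from_cells(cells)
        res = classify_ith(hist, fit_options, ith_options)
        results[tid] = res
        summ = summarize_tumor(cells)
        row = dict(rec)
        row.update(
            ith_label=res.label,
            chosen_k=res.chosen_k,
            overall_mean=res.overall_mean,
            pi_low=res.low_component[0] if res.low_component else np.nan,
            mu_low=res.low_component[1] if res.low_component else np.nan,
            fish_ratio=summ.fish_ratio,
        )
        rows.append(row)
    if not rows:
        raise ValueError("no classifiable tumors in cohort")
    table = pd.DataFrame(rows)
    prevalence = float((table["ith_label"] == "HH").mean())
    group_ratio = {
        label: float(sub["fish_ratio"].mean())
        for label, sub in table.groupby("ith_label")
    }
    return CohortClassification(table=table, results=results,
                                prevalence=prevalence,
                                group_mean_fish_ratio=group_ratio,
                                excluded=excluded)
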