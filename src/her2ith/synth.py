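"""Seeded simulation of clonally mixed tumors, FISH histograms, and cohorts.

The generator mirrors the assumptions of the downstream analysis.  A tumor is
a mixture of one or two cellular clones; each clone contributes per-nucleus
HER2 signal counts drawn from a discretized (rounded, floored at zero) normal
distribution, so the generative family matches the Gaussian mixture fitted
later and parameter recovery is well posed.  CEP17 reference signals are
simulated around two copies per nucleus (diploid centromere), sd 0.3.

A cohort couples the planted high-/low-heterogeneity (HH/LH) label of each
tumor with clinicopathological covariates (ER, PgR, grade, menopause, nodal
status, ...) and a binary pathological-complete-response (pCR) outcome, both
drawn from conditional probability tables.

Randomness: one integer master seed; per-tumor generators are derived with
``numpy.random.SeedSequence(seed).spawn`` (child 0 drives cohort-level draws,
child ``i`` drives tumor ``i``), which is stable across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .histogram import CellCounts, histogram_from_cells
from .imaging import RenderSpec, render_histogram_image  # noqa: F401  (re-export)

__all__ = [
    "CloneProfile",
    "TumorSpec",
    "CohortSpec",
    "TumorSample",
    "CohortTable",
    "simulate_clone_cells",
    "simulate_tumor",
    "simulate_cohort",
    "render_histogram_image",
    "DEFAULT_COVARIATE_MODEL",
    "DEFAULT_OUTCOME_MODEL",
]


@dataclass(frozen=True)
class CloneProfile:
    """Generative parameters of one cellular clone.

    ``mean_her2``/``sd_her2`` give the (pre-discretization) normal law of
    HER2 signals per nucleus, in copies; ``mean_cep17``/``sd_cep17``
    likewise for the centromere-17 reference.  ``sd_her2 = 0`` is allowed
    as a degenerate zero-variance clone (every nucleus gets the rounded
    mean), useful for exact bookkeeping checks.
    """

    mean_her2: float
    sd_her2: float
    mean_cep17: float = 2.0
    sd_cep17: float = 0.3

    def __post_init__(self):
        for name in ("mean_her2", "sd_her2", "mean_cep17", "sd_cep17"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.mean_her2 <= 0 or self.mean_cep17 <= 0:
            raise ValueError("clone means must be strictly positive")
        if self.sd_her2 < 0 or self.sd_cep17 < 0:
            raise ValueError("clone standard deviations must be non-negative")


@dataclass(frozen=True)
class TumorSpec:
    """One synthetic tumor: 1-2 clones, their fractions, and the planted label."""

    clones: tuple[CloneProfile, ...]
    weights: tuple[float, ...]
    n_cells: int = 60
    true_label: str = "LH"

    def __post_init__(self):
        clones = tuple(self.clones)
        weights = tuple(float(w) for w in self.weights)
        if not 1 <= len(clones) <= 2:
            raise ValueError("a tumor has one or two clones")
        if len(clones) != len(weights):
            raise ValueError("clones and weights must have equal length")
        if any(w <= 0 or w > 1 for w in weights):
            raise ValueError("each clone weight must be in (0, 1]")
        if abs(sum(weights) - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {sum(weights)!r}")
        if self.n_cells < 20:
            raise ValueError("at least 20 nuclei are counted per tumor")
        if self.true_label not in ("HH", "LH"):
            raise ValueError("true_label must be 'HH' or 'LH'")
        object.__setattr__(self, "clones", clones)
        object.__setattr__(self, "weights", weights)


#: Per-covariate category probabilities conditional on the planted HH/LH
#: label.  ER and PgR are drawn jointly (they are correlated in luminal
#: disease); the categories of "er_pgr" are "(er, pgr)" pairs.
DEFAULT_COVARIATE_MODEL: dict[str, dict[str, dict[str, float]]] = {
    "menopause": {
        "HH": {"pre": 12 / 18, "post": 6 / 18},
        "LH": {"pre": 35 / 79, "post": 44 / 79},
    },
    "histology": {
        "HH": {"IDC": 17 / 18, "ILC": 1 / 18},
        "LH": {"IDC": 78 / 79, "ILC": 1 / 79},
    },
    "grade": {
        "HH": {"1": 0.0, "2": 9 / 18, "3": 9 / 18},
        "LH": {"1": 5 / 79, "2": 24 / 79, "3": 50 / 79},
    },
    "tumor_size": {
        "HH": {"T1": 1 / 18, "T2-T4": 17 / 18},
        "LH": {"T1": 6 / 79, "T2-T4": 73 / 79},
    },
    "ln_pre": {
        "HH": {"negative": 3 / 18, "positive": 15 / 18},
        "LH": {"negative": 31 / 79, "positive": 48 / 79},
    },
    "er_pgr": {
        "HH": {
            "positive/positive": 7 / 18,
            "positive/negative": 6 / 18,
            "negative/positive": 0 / 18,
            "negative/negative": 5 / 18,
        },
        "LH": {
            "positive/positive": 19 / 79,
            "positive/negative": 20 / 79,
            "negative/positive": 2 / 79,
            "negative/negative": 38 / 79,
        },
    },
    "her2_ihc": {
        "HH": {"3+": 16 / 18, "2+": 2 / 18},
        "LH": {"3+": 74 / 79, "2+": 5 / 79},
    },
    "stage": {
        "HH": {"I": 0.0, "II": 14 / 18, "III": 4 / 18},
        "LH": {"I": 4 / 79, "II": 60 / 79, "III": 15 / 79},
    },
}

#: pCR probability conditional on (planted label, ER status).
DEFAULT_OUTCOME_MODEL: dict[tuple[str, str], float] = {
    ("HH", "positive"): 3 / 13,
    ("HH", "negative"): 2 / 5,
    ("LH", "positive"): 18 / 39,
    ("LH", "negative"): 33 / 40,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    ``covariate_model`` maps covariate -> label -> category probability
    (rows must sum to 1); ``outcome_model`` maps (label, ER status) -> pCR
    probability.  Defaults emulate a 97-tumor HER2-positive neoadjuvant
    cohort with ~18.6% HH prevalence.
    """

    n_tumors: int = 97
    prevalence_hh: float = 18 / 97
    covariate_model: dict = field(default_factory=lambda: DEFAULT_COVARIATE_MODEL)
    outcome_model: dict = field(default_factory=lambda: DEFAULT_OUTCOME_MODEL)
    seed: int = 0
    n_cells: int = 60

    def __post_init__(self):
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        if not 0.0 <= self.prevalence_hh <= 1.0:
            raise ValueError("prevalence_hh must lie in [0, 1]")
        if self.n_cells < 20:
            raise ValueError("n_cells must be >= 20")
        for cov, table in self.covariate_model.items():
            for label, probs in table.items():
                if any(p < 0 or p > 1 for p in probs.values()):
                    raise ValueError(f"probability outside [0,1] in {cov}/{label}")
                if abs(sum(probs.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{cov}/{label} probabilities do not sum to 1")
        for key, p in self.outcome_model.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"outcome probability outside [0,1] for {key}")


@dataclass(frozen=True)
class TumorSample:
    """Simulated per-nucleus counts plus the planted ground truth."""

    cells: CellCounts
    true_label: str
    spec: TumorSpec
    clone_of_cell: np.ndarray  # clone index per nucleus


@dataclass
class CohortTable:
    """A simulated cohort: covariate/outcome table plus per-tumor cells.

    ``table`` has one row per tumor (tumor_id, planted_label, covariates,
    pcr); ``cells`` maps tumor_id -> :class:`CellCounts`; ``specs`` maps
    tumor_id -> the generating :class:`TumorSpec`.
    """

    table: pd.DataFrame
    cells: dict[str, CellCounts]
    specs: dict[str, TumorSpec]
    seed: int | None = None

    def histogram(self, tumor_id: str):
        return histogram_from_cells(self.cells[tumor_id])

    def to_dir(self, outdir) -> None:
        """Write the cohort CSV plus one per-tumor cell TSV each."""
        from pathlib import Path

        from .histogram import write_cells_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tab = self.table.copy()
        files = []
        for tid in tab["tumor_id"]:
            fname = f"{tid}_cells.tsv"
            write_cells_tsv(self.cells[tid], outdir / fname)
            files.append(fname)
        tab.insert(1, "her2_counts_file", files)
        tab.to_csv(outdir / "cohort.csv", index=False)


def simulate_clone_cells(
    profile: CloneProfile, n: int, rng: np.random.Generator
) -> CellCounts:
    """Draw ``n`` nuclei from one clone: rounded normals floored at zero."""
    if n < 1:
        raise ValueError("n must be >= 1")
    her2 = np.rint(rng.normal(profile.mean_her2, profile.sd_her2, size=n))
    cep17 = np.rint(rng.normal(profile.mean_cep17, profile.sd_cep17, size=n))
    return CellCounts(
        her2=np.maximum(her2, 0).astype(np.int64),
        cep17=np.maximum(cep17, 0).astype(np.int64),
    )


def simulate_tumor(spec: TumorSpec, rng: np.random.Generator) -> TumorSample:
    """Draw one tumor: nuclei assigned to clones by weight, then counted."""
    assignment = rng.choice(len(spec.clones), size=spec.n_cells, p=spec.weights)
    her2 = np.empty(spec.n_cells, dtype=np.int64)
    cep17 = np.empty(spec.n_cells, dtype=np.int64)
    for i, clone in enumerate(spec.clones):
        mask = assignment == i
        k = int(mask.sum())
        if k == 0:
            continue
        drawn = simulate_clone_cells(clone, k, rng)
        her2[mask] = drawn.her2
        cep17[mask] = drawn.cep17
    return TumorSample(
        cells=CellCounts(her2=her2, cep17=cep17),
        true_label=spec.true_label,
        spec=spec,
        clone_of_cell=assignment,
    )


def _draw_hh_spec(rng: np.random.Generator, n_cells: int) -> TumorSpec:
    """A biphasic tumor: a low-copy subclone (<2 copies) under an amplified bulk.

    The overall mean copy number M targets ~5 (FISH ratio ~2.5); the
    amplified-clone mean is solved from M so the mixture mean is controlled.
    """
    pi_low = rng.uniform(0.25, 0.45)
    mu_low = rng.uniform(1.2, 1.8)
    target_mean = float(np.clip(rng.normal(5.0, 0.7), 4.2, 6.5))
    sd_low, sd_high = 0.4, 1.0
    mu_high = (target_mean - pi_low * mu_low) / (1.0 - pi_low)
    # biphasic means well separated: two modes at least 4 bulk-sds apart
    mu_high = max(mu_high, mu_low + 4.0 * max(sd_low, sd_high) + 1e-9)
    clones = (
        CloneProfile(mean_her2=mu_low, sd_her2=sd_low),
        CloneProfile(mean_her2=mu_high, sd_her2=sd_high),
    )
    return TumorSpec(clones=clones, weights=(pi_low, 1.0 - pi_low),
                     n_cells=n_cells, true_label="HH")


def _draw_lh_spec(rng: np.random.Generator, n_cells: int) -> TumorSpec:
    """A monophasic amplified tumor (single clone, FISH ratio ~5.3 +/- 2.2)."""
    mu = float(np.clip(rng.normal(10.6, 4.4), 4.5, 18.0))
    sd = rng.uniform(1.0, 2.0)
    return TumorSpec(clones=(CloneProfile(mean_her2=mu, sd_her2=sd),),
                     weights=(1.0,), n_cells=n_cells, true_label="LH")


def draw_tumor_spec(label: str, rng: np.random.Generator, n_cells: int = 60) -> TumorSpec:
    """Sample a tumor's generative parameters given its planted label."""
    return (_draw_hh_spec if label == "HH" else _draw_lh_spec)(rng, n_cells)


def _draw_category(probs: dict[str, float], rng: np.random.Generator) -> str:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=p / p.sum())]


def simulate_cohort(spec: CohortSpec) -> CohortTable:
    """Simulate a full cohort, reproducibly from ``spec.seed``.

    Labels are Bernoulli(prevalence_hh); covariates and pCR come from the
    conditional tables; per-tumor counts from label-conditional clone draws.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_tumors + 1)
    rng = np.random.default_rng(children[0])

    labels = np.where(rng.random(spec.n_tumors) < spec.prevalence_hh, "HH", "LH")
    rows, cells, specs = [], {}, {}
    for i, label in enumerate(labels):
        tid = f"T{i + 1:03d}"
        row: dict[str, object] = {"tumor_id": tid, "planted_label": label}
        for cov, table in spec.covariate_model.items():
            cat = _draw_category(table[label], rng)
            if cov == "er_pgr":
                er, pgr = cat.split("/")
                row["er"], row["pgr"] = er, pgr
            else:
                row[cov] = cat
        p_pcr = spec.outcome_model[(label, row.get("er", "negative"))]
        row["pcr"] = int(rng.random() < p_pcr)

        trng = np.random.default_rng(children[i + 1])
        tspec = draw_tumor_spec(label, trng, spec.n_cells)
        sample = simulate_tumor(tspec, trng)
        cells[tid] = sample.cells
        specs[tid] = tspec
        rows.append(row)

    cols = ["tumor_id", "planted_label", "menopause", "histology", "grade",
            "tumor_size", "ln_pre", "er", "pgr", "her2_ihc", "stage", "pcr"]
    table = pd.DataFrame(rows)
    table = table[[c for c in cols if c in table.columns]]
    return CohortTable(table=table, cells=cells, specs=specs, seed=spec.seed)
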