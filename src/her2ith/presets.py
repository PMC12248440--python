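"""The 97-tumor reference cohort preset.

``paper97`` builds a fully determined cohort of 97 HER2-positive tumors —
18 high-heterogeneity (HH), 79 low-heterogeneity (LH) — whose covariate and
outcome *counts are assigned, not sampled*, so every published 2x2 margin
is reproduced exactly: pCR x {ER, PgR, grade, heterogeneity}, heterogeneity
x {grade, menopause, histology, tumor size, nodal status, IHC, stage}, and
the joint heterogeneity x ER x PgR breakdown (HH frequency 7/26 among
ER+/PgR+ tumors, etc.).

The printed tables only pin pairwise margins; a consistent patient-level
joint (heterogeneity x ER x PgR x grade x pCR) was obtained once by integer
feasibility over the 32 joint cells with all pairwise margins as equality
constraints, and is frozen in ``_JOINT97`` below.  Covariates that do not
interact with the outcome (menopause, histology, size, nodal status, IHC,
stage) are dealt out deterministically within each heterogeneity group to
match the group counts.

Only the per-nucleus signal counts are stochastic: each tumor's cells are
drawn from label-conditional clone mixtures (seeded, reproducible), so the
mixture/classification machinery can run on the preset end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import CohortTable, draw_tumor_spec, simulate_tumor

__all__ = ["paper97"]

# (het, er, pgr, grade_band, pcr) -> patient count; grade_band "1-2" or "3".
# Frozen integer-feasible joint consistent with every published margin.
_JOINT97: list[tuple[str, str, str, str, int, int]] = [
    ("HH", "positive", "positive", "1-2", 0, 6),
    ("HH", "positive", "positive", "3", 1, 1),
    ("HH", "positive", "negative", "1-2", 1, 2),
    ("HH", "positive", "negative", "3", 0, 4),
    ("HH", "negative", "negative", "1-2", 1, 1),
    ("HH", "negative", "negative", "3", 0, 3),
    ("HH", "negative", "negative", "3", 1, 1),
    ("LH", "positive", "positive", "3", 0, 13),
    ("LH", "positive", "positive", "3", 1, 6),
    ("LH", "positive", "negative", "1-2", 0, 8),
    ("LH", "positive", "negative", "1-2", 1, 12),
    ("LH", "negative", "positive", "1-2", 1, 2),
    ("LH", "negative", "negative", "1-2", 0, 7),
    ("LH", "negative", "negative", "3", 1, 31),
]

# per-group deals for covariates that only need heterogeneity margins
# (counts from the published characteristics table; HH n=18, LH n=79)
_GROUP_DEALS: dict[str, dict[str, list[tuple[str, int]]]] = {
    "menopause": {
        "HH": [("pre", 12), ("post", 6)],
        "LH": [("pre", 35), ("post", 44)],
    },
    "histology": {
        "HH": [("ILC", 1), ("IDC", 17)],
        "LH": [("ILC", 1), ("IDC", 78)],
    },
    "tumor_size": {
        "HH": [("T1", 1), ("T2-T4", 17)],
        "LH": [("T1", 6), ("T2-T4", 73)],
    },
    "ln_pre": {
        "HH": [("negative", 3), ("positive", 15)],
        "LH": [("negative", 31), ("positive", 48)],
    },
    "her2_ihc": {
        "HH": [("2+", 2), ("3+", 16)],
        "LH": [("2+", 5), ("3+", 74)],
    },
    "stage": {
        "HH": [("II", 14), ("III", 4)],
        "LH": [("I", 4), ("II", 60), ("III", 15)],
    },
}

# split of the grade "1-2" band into grades 1 and 2 (HH has no grade-1)
_GRADE1_COUNT = {"HH": 0, "LH": 5}


def _deal(deal: list[tuple[str, int]]) -> list[str]:
    out: list[str] = []
    for value, count in deal:
        out.extend([value] * count)
    return out


def paper97(seed: int = 0, n_cells: int = 60) -> CohortTable:
    """Build the reference 97-tumor cohort (counts assigned by construction).

    Parameters
    ----------
    seed : int
        Drives only the per-tumor signal-count draws; the covariate/outcome
        table is identical for every seed.
    n_cells : int
        Nuclei counted per tumor (>= 20).
    """
    rows: list[dict[str, object]] = []
    for het, er, pgr, band, pcr, count in _JOINT97:
        for _ in range(count):
            rows.append({
                "planted_label": het, "er": er, "pgr": pgr,
                "grade_band": band, "pcr": pcr,
            })

    # deterministic within-group deals for the remaining covariates
    by_group: dict[str, list[int]] = {"HH": [], "LH": []}
    for i, row in enumerate(rows):
        by_group[row["planted_label"]].append(i)
    for cov, deals in _GROUP_DEALS.items():
        for label, idxs in by_group.items():
            values = _deal(deals[label])
            assert len(values) == len(idxs)
            for i, v in zip(idxs, values):
                rows[i][cov] = v
    for label, idxs in by_group.items():
        ones_left = _GRADE1_COUNT[label]
        for i in idxs:
            if rows[i]["grade_band"] == "3":
                rows[i]["grade"] = "3"
            elif ones_left > 0:
                rows[i]["grade"] = "1"
                ones_left -= 1
            else:
                rows[i]["grade"] = "2"
        assert ones_left == 0
    for row in rows:
        del row["grade_band"]

    # seeded per-tumor cells, same splitting rule as simulate_cohort
    children = np.random.SeedSequence(seed).spawn(len(rows) + 1)
    cells, specs = {}, {}
    for i, row in enumerate(rows):
        tid = f"P{i + 1:03d}"
        row["tumor_id"] = tid
        trng = np.random.default_rng(children[i + 1])
        tspec = draw_tumor_spec(str(row["planted_label"]), trng, n_cells)
        sample = simulate_tumor(tspec, trng)
        cells[tid] = sample.cells
        specs[tid] = tspec

    cols = ["tumor_id", "planted_label", "menopause", "histology", "grade",
            "tumor_size", "ln_pre", "er", "pgr", "her2_ihc", "stage", "pcr"]
    table = pd.DataFrame(rows)[cols]
    return CohortTable(table=table, cells=cells, specs=specs, seed=seed)
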