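"""Small reference datasets shipped with the package."""

from __future__ import annotations

import numpy as np

from .cohort_stats import CATEGORY3, ContingencyTable

__all__ = ["load_reference_distribution", "reconstruct_reference_cohort"]

# Published distribution of the three Erlangen Score categories across the
# four diagnostic groups of a single-centre memory-clinic cohort
# (66 neurologic controls, 74 stable MCI, 70 MCI-to-AD progressors,
# 168 AD-dementia patients).  Used as the worked example for the ordinal
# statistics stage.
_REFERENCE_COUNTS = {
    "Control": [37, 28, 1],
    "MCI-Stable": [29, 25, 20],
    "MCI-AD": [3, 16, 51],
    "ADD": [9, 35, 124],
}


def load_reference_distribution() -> ContingencyTable:
    """The published 4x3 group-by-category table (n = 378)."""
    return ContingencyTable.from_counts(_REFERENCE_COUNTS, categories=list(CATEGORY3))


# Representative biomarker panels for each three-level category, built from
# the published group medians (improbable/probable) and a clear-cut
# amyloid-only alteration (possible).  Synthetic stand-ins: only the
# *category* of each reconstructed subject is meaningful.
_CATEGORY_PANELS = {
    "improbable": dict(abeta42=852.9, abeta40=8833.0, abeta42_40_ratio=0.100,
                       tau=178.3, ptau181=29.6),
    "possible": dict(abeta42=500.0, abeta40=10000.0, abeta42_40_ratio=0.050,
                     tau=178.3, ptau181=29.6),
    "probable": dict(abeta42=459.6, abeta40=10379.0, abeta42_40_ratio=0.046,
                     tau=448.0, ptau181=59.0),
}


def reconstruct_reference_cohort() -> "pd.DataFrame":
    """Synthetic cohort frame whose category counts equal the published table.

    Each subject gets a representative biomarker panel for their category,
    so re-scoring the frame reproduces the published 4x3 distribution
    exactly.  MCI progressors carry an event before 3 years, stable MCI an
    event-free follow-up beyond it; demographics are filled with neutral
    constants.  Useful as the worked example for the full pipeline.
    """
    import pandas as pd

    from .simulate import HazardSpec, progression_cdf, progression_time_from_uniform

    table = load_reference_distribution()
    spec = HazardSpec()
    rng = np.random.default_rng(20190105)   # fixed: the reconstruction is a constant
    rows = []
    i = 0
    for group in table.groups:
        for cat in table.categories:
            for _ in range(int(table.counts.loc[group, cat])):
                row = dict(id=f"R{i:04d}", group=group,
                           age=55.0 + (i % 30), female=float(i % 2),
                           apoe4=np.nan, mmse=np.nan,
                           followup_years=np.nan, event=np.nan,
                           **_CATEGORY_PANELS[cat])
                if group == "MCI-AD":
                    # event time drawn from the piecewise hazard of the
                    # category, conditioned on progression within 8 years
                    p_max = progression_cdf(8.0, cat, spec)
                    surv = 1.0 - rng.uniform() * p_max
                    row.update(followup_years=progression_time_from_uniform(surv, cat, spec),
                               event=1.0, apoe4=float(i % 2), mmse=22.0 + (i % 7))
                elif group == "MCI-Stable":
                    row.update(followup_years=rng.uniform(3.2, 10.0),
                               event=0.0, apoe4=float(i % 3 == 0), mmse=24.0 + (i % 6))
                rows.append(row)
                i += 1
    from .io import COHORT_COLUMNS
    return pd.DataFrame(rows)[COHORT_COLUMNS]
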