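"""Model-matrix construction shared by the outcome and propensity models."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .schema import TREATMENT_COL, CovariateSchema


def design_matrix(
    table: pd.DataFrame,
    schema: CovariateSchema,
    include_treatment: bool = True,
) -> pd.DataFrame:
    """Numeric model matrix: binary and continuous covariates as floats,
    categorical covariates as reference-coded (drop-first) level indicators
    named ``name=level``, and optionally the treatment column last."""
    cols: dict[str, np.ndarray] = {}
    for cov in schema.entries:
        if cov.name not in table.columns:
            raise KeyError(f"covariate {cov.name!r} missing from table")
        if cov.kind == "categorical":
            vals = table[cov.name].astype(str)
            for lev in cov.levels[1:]:
                cols[f"{cov.name}={lev}"] = (vals == lev).to_numpy(dtype=float)
            # NaN rows: propagate missingness through every indicator
            nan_mask = table[cov.name].isna().to_numpy()
            if nan_mask.any():
                for lev in cov.levels[1:]:
                    arr = cols[f"{cov.name}={lev}"]
                    arr[nan_mask] = np.nan
        else:
            cols[cov.name] = table[cov.name].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=table.index)
    if include_treatment:
        if TREATMENT_COL not in table.columns:
            raise KeyError("table has no treatment column")
        X[TREATMENT_COL] = table[TREATMENT_COL].to_numpy(dtype=float)
    return X
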