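"""Clinical cohort handling: table schema, train/test split, per-scanner
z-score harmonization, and SMOTE class rebalancing.

The clinical table carries per-patient covariates (age at surgery,
pre-/post-operative PSA, Gleason score, T stage, margin status, CAPRA-S),
the scanner stratum, and the survival outcome (biochemical-recurrence
event indicator and time to event/censoring in months).  Categorical
covariates are remapped to ordinal codes by construction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "CLINICAL_COLUMNS",
    "COVARIATE_COLUMNS",
    "SplitAssignment",
    "HarmonizationParams",
    "validate_cohort",
    "load_cohort",
    "save_cohort",
    "split_cohort",
    "zscore_by_scanner",
    "apply_smote",
]

#: Full schema of the clinical table (one row per patient).
CLINICAL_COLUMNS = (
    "patient_id",
    "age",            # years at surgery
    "psa_pre",        # pre-operative PSA, ng/mL
    "psa_post",       # post-operative PSA, ng/mL
    "gleason",        # ordinal Gleason score
    "t_stage",        # ordinal: 0 = pT2, 1 = pT3a, 2 = pT3b
    "margins",        # ordinal: 0 = R0, 1 = R1
    "capra_s",        # CAPRA-S score (given covariate, not recomputed)
    "scanner",        # "A" (1.5T-like stratum) or "B" (3T-like stratum)
    "event",          # biochemical recurrence indicator, 0/1
    "time_months",    # time to BCR or censoring, > 0
)

#: Clinical covariates entering the models (identifiers/outcome excluded).
COVARIATE_COLUMNS = (
    "age", "psa_pre", "psa_post", "gleason", "t_stage", "margins", "capra_s",
)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants; returns the frame for chaining."""
    missing = set(CLINICAL_COLUMNS) - set(cohort.columns)
    if missing:
        raise ValueError(f"clinical table is missing columns {sorted(missing)}")
    if not cohort["event"].isin((0, 1)).all():
        raise ValueError("event must be 0/1")
    if (cohort["time_months"] <= 0).any():
        raise ValueError("time_months must be positive")
    if (cohort[["psa_pre", "psa_post"]] < 0).any().any():
        raise ValueError("PSA values must be non-negative")
    return cohort


def load_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def save_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(cohort).to_csv(path, index=False)


@dataclass
class SplitAssignment:
    """Per-patient train/test labels, reproducible from the seed."""

    labels: pd.Series  # index: patient_id, values in {"train", "test"}
    seed: int

    @property
    def train_ids(self) -> list:
        return list(self.labels.index[self.labels == "train"])

    @property
    def test_ids(self) -> list:
        return list(self.labels.index[self.labels == "test"])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"seed": self.seed, "labels": self.labels.to_dict()},
                       indent=1, default=str)
        )


def split_cohort(
    cohort: pd.DataFrame, seed: int, train_fraction: float = 2 / 3
) -> SplitAssignment:
    """Random 2:1 train/test split, stratified on (event, scanner).

    Within each stratum the train share is ``round(f * n)`` (half-up), so
    both sides carry both scanners and both outcome classes wherever the
    stratum size allows.  Strata with fewer than 3 members are assigned
    best-effort with a warning.
    """
    validate_cohort(cohort)
    rng = np.random.default_rng(seed)
    labels = pd.Series(index=cohort["patient_id"].values, dtype=object)
    for (_ev, _sc), grp in cohort.groupby(["event", "scanner"], sort=True):
        ids = grp["patient_id"].to_numpy()
        if len(ids) < 3:
            warnings.warn(
                f"stratum (event={_ev}, scanner={_sc}) has {len(ids)} "
                "members; assigning best-effort"
            )
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))
        labels[ids[perm[:n_train]]] = "train"
        labels[ids[perm[n_train:]]] = "test"
    return SplitAssignment(labels, seed)


@dataclass
class HarmonizationParams:
    """Per (scanner, feature) mean/SD used for z-scoring on one cohort side."""

    side: str
    means: pd.DataFrame   # index: scanner, columns: features
    sds: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "side": self.side,
            "means": self.means.to_dict(),
            "sds": self.sds.to_dict(),
        }, indent=1))


def zscore_by_scanner(
    table: pd.DataFrame, scanner: pd.Series, side: str = "train"
) -> tuple[pd.DataFrame, HarmonizationParams]:
    """Z-score each feature to mean 0 / SD 1 within each scanner group.

    SD uses the n-1 denominator.  Features with zero variance inside a
    group (or a group of size 1) are set to 0 there with a warning.
    """
    scanner = scanner.reindex(table.index)
    out = table.copy().astype(float)
    means, sds = {}, {}
    for sc, idx in table.groupby(scanner).groups.items():
        block = table.loc[idx].astype(float)
        mu = block.mean()
        sd = block.std(ddof=1) if len(idx) > 1 else pd.Series(0.0, index=block.columns)
        degenerate = ~(sd > 0)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-variance feature(s) in scanner "
                f"group {sc!r} ({side}); set to 0"
            )
        safe_sd = sd.where(~degenerate, 1.0)
        z = (block - mu) / safe_sd
        z.loc[:, degenerate] = 0.0
        out.loc[idx] = z
        means[sc], sds[sc] = mu, sd
    params = HarmonizationParams(side, pd.DataFrame(means).T, pd.DataFrame(sds).T)
    return out, params


def apply_smote(
    table: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Balance classes with the synthetic minority oversampling technique.

    Each synthetic minority row is ``x + u * (x_nn - x)`` with
    ``u ~ Uniform(0, 1)`` and ``x_nn`` drawn among the ``k`` nearest
    minority neighbours of ``x`` (Euclidean distance in the supplied
    feature space).  Original rows are preserved unchanged; the output is
    exactly balanced.  An already balanced input is returned as-is.
    """
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE needs exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return table.copy(), y.copy()
    if n_min < 2:
        raise ValueError("minority class needs at least 2 members for SMOTE")
    if k > n_min - 1:
        warnings.warn(f"k={k} reduced to {n_min - 1} (minority size {n_min})")
        k = n_min - 1

    rng = np.random.default_rng(seed)
    x_min = table.loc[np.asarray(y == minority)].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    neighbors = nn.kneighbors(x_min, return_distance=False)[:, 1:]

    n_syn = n_maj - n_min
    base = rng.integers(0, n_min, size=n_syn)
    pick = neighbors[base, rng.integers(0, k, size=n_syn)]
    u = rng.uniform(0.0, 1.0, size=(n_syn, 1))
    synthetic = x_min[base] + u * (x_min[pick] - x_min[base])

    syn_df = pd.DataFrame(
        synthetic,
        columns=table.columns,
        index=[f"synthetic_{i}" for i in range(n_syn)],
    )
    out = pd.concat([table, syn_df])
    out_y = np.concatenate([y, np.full(n_syn, minority)])
    return out, out_y
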