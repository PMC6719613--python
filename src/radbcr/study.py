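"""End-to-end study orchestration, statsmodels-style.

:class:`RecurrenceStudy` is the model object: it holds the per-patient
feature table (extracted from the wavelet sub-bands of each sequence) and
the clinical table, and its :meth:`~RecurrenceStudy.fit` runs the whole
analysis for one seed — stratified 2:1 split, per-side per-scanner
z-scoring, SMOTE + stability selection on the training side, train-side
cutoffs, and the three-model evaluation on both sides — returning a
:class:`StudyResults` with the selection evidence, univariate tables,
model comparison, and a ``summary()`` text report.

Stage ordering guarantees that no test-side value influences any
train-side decision; :meth:`StudyResults.train_artifacts` serializes every
train-side decision so the guarantee is testable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from . import __version__
from .cohort import (
    COVARIATE_COLUMNS,
    SplitAssignment,
    load_cohort,
    split_cohort,
    validate_cohort,
    zscore_by_scanner,
)
from .imaging import DiscretizationScheme, load_mask, load_volume
from .selection import SelectionConfig, SelectionResult, run_selection
from .survival import ModelComparison, evaluate_models, univariate_report
from .synthetic import SyntheticPatient
from .texture import extract_all
from .wavelets import decompose

__all__ = ["StudyConfig", "RecurrenceStudy", "StudyResults",
           "cohort_characteristics"]

DEFAULT_SCHEMES = (DiscretizationScheme.fbn(8), DiscretizationScheme.fbn(32))


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one study run."""

    schemes: tuple[DiscretizationScheme, ...] = DEFAULT_SCHEMES
    connectivity: int = 26
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    train_fraction: float = 2 / 3
    max_factors: int = 2

    def digest(self) -> str:
        blob = json.dumps({
            "schemes": [s.label for s in self.schemes],
            "connectivity": self.connectivity,
            "selection": vars(self.selection),
            "train_fraction": self.train_fraction,
            "max_factors": self.max_factors,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def cohort_characteristics(
    cohort: pd.DataFrame, split: SplitAssignment
) -> pd.DataFrame:
    """Train-vs-test characteristics table with two-sample p-values
    (Welch t-test for continuous variables, chi-square for ordinals)."""
    continuous = ("age", "psa_pre", "psa_post", "time_months")
    categorical = ("gleason", "t_stage", "margins", "scanner", "event")
    c = cohort.set_index("patient_id")
    tr = c.loc[split.train_ids]
    te = c.loc[split.test_ids]
    rows = []
    for var in continuous:
        p = float(stats.ttest_ind(tr[var], te[var], equal_var=False).pvalue)
        rows.append({"variable": var, "train": tr[var].mean(),
                     "test": te[var].mean(), "p_value": p})
    for var in categorical:
        tab = pd.crosstab(c[var], split.labels.reindex(c.index))
        if tab.shape[0] < 2:
            p = 1.0
        else:
            p = float(stats.chi2_contingency(tab.to_numpy())[1])
        rows.append({
            "variable": var,
            "train": tr[var].astype(str).value_counts().to_dict(),
            "test": te[var].astype(str).value_counts().to_dict(),
            "p_value": p,
        })
    return pd.DataFrame(rows).set_index("variable")


class RecurrenceStudy:
    """Radiomics + clinical model of biochemical recurrence.

    Parameters
    ----------
    feature_table
        Patients x feature-variants matrix (index: patient_id, columns:
        ``SEQ|SUBBAND|SCHEME|FEATURE`` keys).
    cohort
        Clinical table in the :data:`radbcr.cohort.CLINICAL_COLUMNS`
        schema.
    config
        Study configuration; defaults follow the documented workflow.
    """

    def __init__(
        self,
        feature_table: pd.DataFrame,
        cohort: pd.DataFrame,
        config: StudyConfig | None = None,
    ) -> None:
        self.config = config or StudyConfig()
        self.cohort = validate_cohort(cohort).reset_index(drop=True)
        ids = list(self.cohort["patient_id"])
        missing = set(ids) - set(feature_table.index)
        if missing:
            raise ValueError(f"feature table lacks rows for patients {sorted(missing)[:5]}")
        self.feature_table = feature_table.loc[ids]

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_cohort(
        cls,
        patients: list[SyntheticPatient],
        config: StudyConfig | None = None,
    ) -> "RecurrenceStudy":
        """Extract features from in-memory patients (e.g. a synthetic
        cohort) and assemble the model."""
        from .synthetic import cohort_dataframe

        config = config or StudyConfig()
        rows = {}
        for p in patients:
            banks = {seq: decompose(vol) for seq, vol in p.images.items()}
            rows[p.patient_id] = extract_all(
                banks, p.mask, list(config.schemes), config.connectivity,
                spacing=p.images["ADC"].spacing,
            )
        table = pd.DataFrame.from_dict(rows, orient="index")
        return cls(table, cohort_dataframe(patients), config)

    @classmethod
    def from_directory(
        cls, path: str | Path, config: StudyConfig | None = None
    ) -> "RecurrenceStudy":
        """Load a study directory (clinical.csv + images/<id>_{T2,ADC,mask}
        NIfTIs) and extract features.  A missing or unreadable file aborts
        with the offending patient id."""
        config = config or StudyConfig()
        path = Path(path)
        cohort = load_cohort(path / "clinical.csv")
        rows = {}
        for pid in cohort["patient_id"]:
            try:
                banks = {
                    seq: decompose(load_volume(path / "images" / f"{pid}_{seq}.nii.gz"))
                    for seq in ("ADC", "T2")
                }
                mask = load_mask(path / "images" / f"{pid}_mask.nii.gz")
                spacing = load_volume(
                    path / "images" / f"{pid}_ADC.nii.gz"
                ).spacing
            except Exception as exc:
                raise RuntimeError(
                    f"stage extract failed for patient {pid}: {exc}"
                ) from exc
            rows[pid] = extract_all(
                banks, mask, list(config.schemes), config.connectivity,
                spacing=spacing,
            )
        return cls(pd.DataFrame.from_dict(rows, orient="index"), cohort, config)

    # -- fitting ------------------------------------------------------------

    def fit(self, seed: int = 0) -> "StudyResults":
        """Run split -> harmonize -> select -> cutoffs -> evaluate."""
        cfg = self.config
        cohort = self.cohort.set_index("patient_id", drop=False)
        split = split_cohort(self.cohort, seed, cfg.train_fraction)

        # ---- training side only: every decision is made here
        train_ids = split.train_ids
        scanner = cohort["scanner"]
        z_train, params_train = zscore_by_scanner(
            self.feature_table.loc[train_ids], scanner.loc[train_ids], "train"
        )
        y_train = cohort.loc[train_ids, "event"].to_numpy(dtype=int)
        selection = run_selection(z_train, y_train, cfg.selection, seed)
        clinical_train = cohort.loc[train_ids, list(COVARIATE_COLUMNS)]
        outcome_train = cohort.loc[train_ids, ["event", "time_months"]]
        univariate_train = univariate_report(
            pd.concat([z_train[selection.selected], clinical_train], axis=1),
            y_train,
        )

        # ---- testing side: frozen train-side decisions applied
        test_ids = split.test_ids
        z_test, params_test = zscore_by_scanner(
            self.feature_table.loc[test_ids], scanner.loc[test_ids], "test"
        )
        clinical_test = cohort.loc[test_ids, list(COVARIATE_COLUMNS)]
        outcome_test = cohort.loc[test_ids, ["event", "time_months"]]
        models = evaluate_models(
            z_train[selection.selected], z_test[selection.selected],
            clinical_train, clinical_test,
            outcome_train, outcome_test,
            max_factors=cfg.max_factors,
        )

        manifest = {
            "package_version": __version__,
            "config_digest": self.config.digest(),
            "seed": seed,
            "n_patients": len(self.cohort),
            "n_features": self.feature_table.shape[1],
        }
        return StudyResults(
            config=cfg, seed=seed, split=split,
            harmonization={"train": params_train, "test": params_test},
            selection=selection,
            univariate_train=univariate_train,
            models=models,
            characteristics=cohort_characteristics(self.cohort, split),
            manifest=manifest,
        )


@dataclass
class StudyResults:
    """Fitted study: selection evidence, univariate tables, three-model
    comparison on both cohort sides, and the reproducibility manifest."""

    config: StudyConfig
    seed: int
    split: SplitAssignment
    harmonization: dict
    selection: SelectionResult
    univariate_train: pd.DataFrame
    models: ModelComparison
    characteristics: pd.DataFrame
    manifest: dict

    @property
    def selected_features(self) -> list[str]:
        return self.selection.selected

    def train_artifacts(self) -> str:
        """Deterministic JSON of every train-side decision (split of the
        train ids, harmonization parameters, selection, frozen cutoffs) —
        the object the leakage guard compares byte-for-byte."""
        payload = {
            "train_ids": self.split.train_ids,
            "harmonization_train": {
                "means": self.harmonization["train"].means.round(12).to_dict(),
                "sds": self.harmonization["train"].sds.round(12).to_dict(),
            },
            "selected": self.selection.selected,
            "evidence_means": {
                k: round(e.mean_abs_pc, 12)
                for k, e in self.selection.evidence.items()
            },
            "factors": {
                m: [vars(f) for f in fs]
                for m, fs in self.models.factors.items()
            },
            "score_cutoffs": self.models.score_cutoffs,
            "univariate_train": self.univariate_train.round(12).to_dict(),
        }
        return json.dumps(payload, sort_keys=True, default=str)

    def summary(self) -> str:
        lines = []
        lines.append("Biochemical recurrence radiomics study")
        lines.append("=" * 54)
        n_tr, n_te = len(self.split.train_ids), len(self.split.test_ids)
        lines.append(f"Patients: {n_tr + n_te} (train {n_tr} / test {n_te}); "
                     f"seed {self.seed}; config {self.manifest['config_digest']}")
        lines.append(f"Feature variants extracted: {self.manifest['n_features']}")
        lines.append("")
        lines.append(f"Selected features ({len(self.selection.selected)}):")
        for k in self.selection.selected:
            ev = self.selection.evidence[k]
            lines.append(f"  {k}  mean|PC|={ev.mean_abs_pc:.3f}")
        lines.append("")
        lines.append("Univariate (training side):")
        lines.append(self.univariate_train.round(4).to_string())
        lines.append("")
        lines.append("Model comparison:")
        lines.append(self.models.summary_table().round(4).to_string(index=False))
        lines.append("")
        for entry in self.models.audit:
            lines.append("  " + entry)
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.split.to_json(outdir / "split.json")
        self.harmonization["train"].to_json(outdir / "harmonization_train.json")
        self.harmonization["test"].to_json(outdir / "harmonization_test.json")
        self.selection.to_json(outdir / "selection.json")
        self.univariate_train.to_csv(outdir / "univariate_train.csv")
        self.models.to_json(outdir / "models.json")
        self.characteristics.to_csv(outdir / "characteristics.csv")
        (outdir / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        return outdir
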