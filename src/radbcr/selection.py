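"""Resampling-stability feature selection.

The training table is sub-sampled 100 times at a 2:1 ratio with class
stratification.  For every feature variant the point-biserial Pearson
correlation (PC) with the binary outcome is computed on each subsample; a
variant is *stable* when its absolute PC exceeds 0.3 in at least 95% of
subsamples.  Among the stable variants of each base feature (same
sequence and feature name, different sub-band/discretization) only the
one maximizing the mean |PC| is retained, and the survivors are finally
pruned greedily so that no retained pair correlates above 0.7 in absolute
value, keeping the higher-|PC| member.

Class imbalance is corrected with SMOTE on the whole training table
before any of the above (configurable off for sensitivity analysis).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import apply_smote
from .texture import base_feature

__all__ = [
    "SelectionConfig",
    "StabilityEvidence",
    "SelectionResult",
    "make_subsamples",
    "pearson_with_outcome",
    "stability_check",
    "select_best_variant",
    "prune_correlated",
    "run_selection",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the selection procedure (defaults follow the workflow
    this package implements: 100 subsamples, 2:1 ratio, 95% stability at
    |PC| > 0.3, redundancy pruning at 0.7)."""

    n_subsamples: int = 100
    subsample_fraction: float = 2 / 3
    stability_fraction: float = 0.95   # tau
    pc_threshold: float = 0.3          # rho_min
    redundancy_threshold: float = 0.7  # rho_red
    strict_threshold: bool = True      # "above 0.3" read as strict >
    use_smote: bool = True
    smote_k: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.pc_threshold < 1):
            raise ValueError("pc_threshold must be in (0, 1)")
        if not (0 < self.stability_fraction <= 1):
            raise ValueError("stability_fraction must be in (0, 1]")
        if not (0 < self.redundancy_threshold < 1):
            raise ValueError("redundancy_threshold must be in (0, 1)")


@dataclass
class StabilityEvidence:
    """Audit trail for one feature variant across all subsamples."""

    key: str
    abs_pcs: np.ndarray
    passed: bool
    mean_abs_pc: float


@dataclass
class SelectionResult:
    """Surviving variants with their evidence and an audit of decisions."""

    selected: list[str]
    evidence: dict[str, StabilityEvidence]
    audit: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected": self.selected,
            "evidence": {
                k: {"passed": bool(e.passed), "mean_abs_pc": float(e.mean_abs_pc)}
                for k, e in self.evidence.items()
            },
            "audit": self.audit,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_subsamples(
    labels: np.ndarray, config: SelectionConfig, seed: int
) -> list[np.ndarray]:
    """Stratified 2:1 index subsets: per class, ``round(f * n_c)`` rows,
    so class proportions stay within one row of the parent's."""
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    class_idx = {c: np.flatnonzero(y == c) for c in np.unique(y)}
    out = []
    for _ in range(config.n_subsamples):
        take = []
        for idx in class_idx.values():
            n_take = int(np.floor(config.subsample_fraction * len(idx) + 0.5))
            take.append(rng.permutation(idx)[:n_take])
        out.append(np.sort(np.concatenate(take)))
    return out


def pearson_with_outcome(values: np.ndarray, labels: np.ndarray) -> float:
    """Point-biserial Pearson correlation of a feature with the 0/1
    outcome; 0 when either argument has zero variance."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def _corr_all_columns(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of x with y; 0 on zero variance."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    num = xc.T @ yc
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / denom, 0.0)
    return r


def stability_flags(
    abs_pcs: np.ndarray, config: SelectionConfig
) -> np.ndarray:
    """Apply the counting rule to an (n_subsamples, n_variants) matrix of
    absolute correlations: pass iff at least ``ceil(tau * n_subsamples)``
    entries exceed the threshold (strictly, by default)."""
    if config.strict_threshold:
        hits = (abs_pcs > config.pc_threshold).sum(axis=0)
    else:
        hits = (abs_pcs >= config.pc_threshold).sum(axis=0)
    need = int(np.ceil(config.stability_fraction * config.n_subsamples))
    return hits >= need


def stability_check(
    table: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig,
    seed: int,
) -> dict[str, StabilityEvidence]:
    """Compute all n_subsamples |PC| values per variant and flag stability.

    No early exit: every correlation is computed so the evidence is a
    complete audit.  The pass rule counts subsamples with |PC| above the
    threshold (strictly, by default) and requires at least
    ``ceil(tau * n_subsamples)`` of them.
    """
    y = np.asarray(labels).astype(int)
    x = table.to_numpy(dtype=float)
    subsets = make_subsamples(y, config, seed)
    abs_pcs = np.empty((len(subsets), x.shape[1]))
    for row, idx in enumerate(subsets):
        abs_pcs[row] = np.abs(_corr_all_columns(x[idx], y[idx].astype(float)))
    passed = stability_flags(abs_pcs, config)
    means = abs_pcs.mean(axis=0)
    return {
        key: StabilityEvidence(key, abs_pcs[:, col], bool(passed[col]),
                               float(means[col]))
        for col, key in enumerate(table.columns)
    }


def select_best_variant(
    evidence: dict[str, StabilityEvidence],
    base_key=base_feature,
) -> list[str]:
    """One variant per base feature: among the stable variants sharing a
    base key, keep the argmax of mean |PC| (ties: lexicographically
    smallest key, logged)."""
    groups: dict[tuple, list[StabilityEvidence]] = {}
    for ev in evidence.values():
        if ev.passed:
            groups.setdefault(base_key(ev.key), []).append(ev)
    winners = []
    for base, group in sorted(groups.items()):
        best = sorted(group, key=lambda e: (-e.mean_abs_pc, e.key))[0]
        ties = [e.key for e in group
                if e.mean_abs_pc == best.mean_abs_pc and e.key != best.key]
        if ties:
            log.info("tie on mean |PC| for base %s: kept %s over %s",
                     base, best.key, ties)
        winners.append(best.key)
    return winners


def prune_correlated(
    table: pd.DataFrame,
    evidence: dict[str, StabilityEvidence],
    candidates: list[str],
    redundancy_threshold: float = 0.7,
) -> SelectionResult:
    """Greedy redundancy pruning: rank candidates by mean |PC| descending
    and accept each iff its absolute Pearson correlation with every
    already-accepted candidate is <= the threshold."""
    ranked = sorted(
        candidates,
        key=lambda k: (-evidence[k].mean_abs_pc, k),
    )
    accepted: list[str] = []
    audit: list[str] = []
    for key in ranked:
        vals = table[key].to_numpy(dtype=float)
        conflict = None
        for kept in accepted:
            r = abs(pearson_with_outcome(vals, table[kept].to_numpy(dtype=float)))
            if r > redundancy_threshold:
                conflict = (kept, r)
                break
        if conflict is None:
            accepted.append(key)
            audit.append(f"accept {key} (mean|PC|={evidence[key].mean_abs_pc:.3f})")
        else:
            audit.append(
                f"discard {key}: |r|={conflict[1]:.3f} with {conflict[0]}"
            )
    return SelectionResult(accepted, {k: evidence[k] for k in candidates}, audit)


def run_selection(
    table: pd.DataFrame,
    labels: np.ndarray,
    config: SelectionConfig,
    seed: int,
    base_key=base_feature,
) -> SelectionResult:
    """Full reduction: SMOTE -> stability check -> best variant per base
    feature -> redundancy pruning.  Reproducible from (inputs, seed).

    Columns containing missing values (features undefined on degenerate
    ROIs) are excluded up front and noted in the audit.
    """
    finite = table.columns[np.isfinite(table.to_numpy(dtype=float)).all(axis=0)]
    dropped = [c for c in table.columns if c not in set(finite)]
    table = table[finite]
    audit_head = [f"drop {c}: non-finite values" for c in dropped]

    if config.use_smote:
        table_aug, labels_aug = apply_smote(
            table, labels, k=config.smote_k, seed=seed
        )
    else:
        table_aug, labels_aug = table, np.asarray(labels).astype(int)

    evidence = stability_check(table_aug, labels_aug, config, seed)
    winners = select_best_variant(evidence, base_key=base_key)
    result = prune_correlated(
        table_aug, evidence, winners, config.redundancy_threshold
    )
    result.audit = audit_head + result.audit
    return result
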