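"""Patient-level, group-stratified dataset splitting.

Scans are grouped by their lesion-class combination (7 groups: IRF, PED,
SRF and their pairings/triple); each patient is assigned the modal group of
their B-scans and patients are partitioned into k outer folds so that every
group is spread as evenly as possible.  The inner model-selection split is
a single stratified patient-level train/validation partition (no inner CV).
No patient ever appears in more than one of train/validation/test within a
fold, which rules out leakage between structurally correlated scans of the
same eye.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("IRF", "PED", "SRF", "IRF+PED", "IRF+SRF", "PED+SRF", "IRF+PED+SRF")


def assign_group(mask: np.ndarray) -> str:
    """Lesion-combination group of one label mask."""
    present = {int(v) for v in np.unique(mask) if v}
    if not present:
        raise ValueError("all-background mask has no lesion group")
    if not present <= {1, 2, 3}:
        raise ValueError(f"unexpected label values {sorted(present)}")
    names = [n for n, v in (("IRF", 1), ("PED", 3), ("SRF", 2)) if v in present]
    return "+".join(names)


@dataclass
class FoldSplit:
    """Outer-fold assignment plus per-fold train/val/test patient sets."""

    fold_of: dict  # patient_id -> outer fold index
    folds: list  # fold -> {"train": [...], "val": [...], "test": [...]}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f, roles in enumerate(self.folds):
            for role, pats in roles.items():
                rows.extend({"patient_id": p, "fold": f, "role": role} for p in pats)
        return pd.DataFrame(rows, columns=["patient_id", "fold", "role"])

    def save(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "FoldSplit":
        df = pd.read_csv(path)
        k = int(df["fold"].max()) + 1
        folds = []
        fold_of = {}
        for f in range(k):
            sub = df[df["fold"] == f]
            roles = {role: sorted(sub[sub["role"] == role]["patient_id"]) for role in
                     ("train", "val", "test")}
            folds.append(roles)
            for p in roles["test"]:
                fold_of[p] = f
        return cls(fold_of=fold_of, folds=folds)


def patient_groups(manifest: pd.DataFrame) -> dict:
    """Modal lesion group per patient (ties broken towards the rarest group)."""
    global_counts = Counter(manifest["groups"])
    out = {}
    for pid, sub in manifest.groupby("patient_id"):
        counts = Counter(sub["groups"])
        top = max(counts.values())
        cands = [g for g, c in counts.items() if c == top]
        out[pid] = min(cands, key=lambda g: (global_counts[g], g))
    return out


def _spread(items: list, k: int, group_sizes: np.ndarray, global_sizes: np.ndarray, rng) -> list:
    """Assign items to folds so the group's per-fold count stays within one
    of balanced; ties go to the globally smallest fold."""
    items = list(items)
    rng.shuffle(items)
    order = rng.permutation(k)  # randomise residual ties deterministically
    assignment = []
    for it in items:
        f = min(range(k), key=lambda f: (group_sizes[f], global_sizes[f], order[f]))
        assignment.append((it, f))
        group_sizes[f] += 1
        global_sizes[f] += 1
    return assignment


def stratified_patient_kfold(manifest: pd.DataFrame, k: int = 5, seed: int = 0,
                             val_fraction: float = 0.2) -> FoldSplit:
    """Partition patients into k folds, stratified by lesion group.

    Patients of each group are spread across folds so the per-fold group
    count differs from the balanced share by at most one patient.  For each
    outer fold the remaining patients are split once more (stratified) into
    train and validation.
    """
    strata = patient_groups(manifest)
    patients = sorted(strata)
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    by_group: dict = {}
    for p in patients:
        by_group.setdefault(strata[p], []).append(p)

    fold_sizes = np.zeros(k, dtype=int)
    fold_of = {}
    # largest groups first so small groups can still even out fold sizes
    for g in sorted(by_group, key=lambda g: (-len(by_group[g]), g)):
        members = sorted(by_group[g])
        # per-group balanced spread: floor/ceil shares only
        sizes = np.zeros(k, dtype=int)
        for p, f in _spread(members, k, sizes, fold_sizes, rng):
            fold_of[p] = f

    folds = []
    for f in range(k):
        test = sorted(p for p in patients if fold_of[p] == f)
        rest = [p for p in patients if fold_of[p] != f]
        train, val = inner_split(rest, strata, val_fraction=val_fraction,
                                 seed=int(rng.integers(0, 2**31 - 1)))
        folds.append({"train": train, "val": val, "test": test})
    return FoldSplit(fold_of=fold_of, folds=folds)


def inner_split(patients: list, strata: dict, val_fraction: float = 0.2, seed: int = 0):
    """Single stratified patient-level train/validation split."""
    if len(patients) < 2:
        raise ValueError("need at least two patients for an inner split")
    if not (0.0 < val_fraction < 1.0):
        raise ValueError("val_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_group: dict = {}
    for p in sorted(patients):
        by_group.setdefault(strata[p], []).append(p)
    total_val = min(len(patients) - 1, max(1, round(val_fraction * len(patients))))
    # largest-remainder allocation of the validation quota over groups
    names = sorted(by_group, key=lambda g: (-len(by_group[g]), g))
    exact = np.array([val_fraction * len(by_group[g]) for g in names])
    quota = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - quota)):
        if quota.sum() >= total_val:
            break
        if quota[i] < len(by_group[names[i]]):
            quota[i] += 1
    val = []
    for g, q in zip(names, quota):
        members = sorted(by_group[g])
        rng.shuffle(members)
        val.extend(members[:q])
    train = sorted(set(patients) - set(val))
    if not train:
        raise ValueError("validation fraction leaves no training patients")
    return train, sorted(val)
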