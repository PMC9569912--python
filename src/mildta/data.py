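"""Drug-target affinity datasets, statistics and train/val/test splitting.

Two on-disk layouts are supported:

* ``pairs-table`` — a CSV/TSV with header columns
  ``drug_id, smiles, target_id, sequence, affinity``, one interaction per row;
* ``deepdta-folder`` — a directory with ``ligands.tsv`` (drug_id, smiles),
  ``proteins.tsv`` (target_id, sequence) and ``affinities.tsv``, a drugs ×
  targets matrix whose empty/NaN cells mean "not measured".

Splitting supports the two standard evaluation regimes: *random* pair-level
5-fold splitting (which leaks entities between train and test whenever a
drug or target participates in several pairs) and the *blind* (cold) split
in which drugs and targets are partitioned first so that test pairs involve
only drugs and targets never seen in training.  Pairs mixing a training
entity with a test entity cannot be placed on either side of a blind split
without leakage and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

__all__ = [
    "DTDataset",
    "SplitAssignment",
    "StatsReport",
    "load_dataset",
    "dataset_stats",
    "random_split",
    "blind_split",
    "overlap_report",
]


@dataclass
class DTDataset:
    """A drug-target affinity dataset: entity tables plus observed pairs."""

    drugs: dict[str, str]  # drug_id -> SMILES
    targets: dict[str, str]  # target_id -> amino-acid sequence
    pairs: list[tuple[str, str, float]]  # (drug_id, target_id, affinity)

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("dataset has no interaction pairs")
        seen: set[tuple[str, str]] = set()
        for i, (d, t, y) in enumerate(self.pairs):
            if d not in self.drugs:
                raise ValueError(f"pair {i} references unknown drug id {d!r}")
            if t not in self.targets:
                raise ValueError(f"pair {i} references unknown target id {t!r}")
            if (d, t) in seen:
                raise ValueError(f"duplicate pair ({d!r}, {t!r}) at index {i}")
            if not np.isfinite(y):
                raise ValueError(f"non-finite affinity at pair index {i}")
            seen.add((d, t))

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (d, self.drugs[d], t, self.targets[t], y) for d, t, y in self.pairs
        ]
        return pd.DataFrame(
            rows, columns=["drug_id", "smiles", "target_id", "sequence", "affinity"]
        )

    def subset(self, indices) -> pd.DataFrame:
        return self.to_frame().iloc[list(indices)].reset_index(drop=True)


@dataclass(frozen=True)
class StatsReport:
    n_targets: int
    n_drugs: int
    n_pairs: int
    sparsity: float  # raw ratio

    def sparsity_rounded(self, digits: int = 4) -> float:
        return round(self.sparsity, digits)

    def to_dict(self) -> dict:
        return {
            "n_targets": self.n_targets,
            "n_drugs": self.n_drugs,
            "n_pairs": self.n_pairs,
            "sparsity": self.sparsity,
        }


@dataclass
class SplitAssignment:
    """Membership of each pair index in train/val/test under one strategy."""

    strategy: str  # "random" | "blind"
    train: list[int]
    val: list[int]
    test: list[int]
    seed: int
    discarded: list[int] = field(default_factory=list)
    overlap: dict = field(default_factory=dict)

    def partitions(self) -> dict[str, list[int]]:
        return {"train": self.train, "val": self.val, "test": self.test}


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_dataset(path: str | Path, format: str = "pairs-table") -> DTDataset:
    """Read a dataset from disk and validate it.

    Malformed affinities and duplicate pairs are rejected with the offending
    row number in the error message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "pairs-table":
        return _load_pairs_table(path)
    if format == "deepdta-folder":
        return _load_deepdta_folder(path)
    raise ValueError(f"unknown dataset format {format!r}")


def _load_pairs_table(path: Path) -> DTDataset:
    df = _read_table(path)
    required = ["drug_id", "smiles", "target_id", "sequence", "affinity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: empty dataset")
    drugs: dict[str, str] = {}
    targets: dict[str, str] = {}
    pairs: list[tuple[str, str, float]] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            y = float(row.affinity)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {row_no}: cannot parse affinity {row.affinity!r}"
            ) from None
        if not np.isfinite(y):
            raise ValueError(f"{path}: row {row_no}: non-finite affinity")
        for table, key, value, kind in (
            (drugs, row.drug_id, row.smiles, "drug"),
            (targets, row.target_id, row.sequence, "target"),
        ):
            if key in table and table[key] != value:
                raise ValueError(
                    f"{path}: row {row_no}: {kind} id {key!r} re-defined with a "
                    "different sequence"
                )
            table[key] = value
        pairs.append((row.drug_id, row.target_id, y))
    try:
        return DTDataset(drugs, targets, pairs)
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def _load_deepdta_folder(path: Path) -> DTDataset:
    if not path.is_dir():
        raise ValueError(f"{path}: deepdta-folder format expects a directory")
    ligands = _read_table(path / "ligands.tsv").set_index("drug_id")["smiles"]
    proteins = _read_table(path / "proteins.tsv").set_index("target_id")["sequence"]
    aff = pd.read_csv(path / "affinities.tsv", sep="\t", index_col=0)
    pairs: list[tuple[str, str, float]] = []
    for d in aff.index.astype(str):
        for t in aff.columns.astype(str):
            y = pd.to_numeric(aff.loc[d, t], errors="coerce")
            if pd.notna(y):
                pairs.append((d, t, float(y)))
    return DTDataset(dict(ligands), dict(proteins), pairs)


def dataset_stats(ds: DTDataset) -> StatsReport:
    """Counts and sparsity = |pairs| / (|drugs| × |targets|)."""
    n_d, n_t, n_p = len(ds.drugs), len(ds.targets), len(ds.pairs)
    return StatsReport(
        n_targets=n_t, n_drugs=n_d, n_pairs=n_p, sparsity=n_p / (n_d * n_t)
    )


def random_split(
    ds: DTDataset, n_folds: int = 5, test_fold: int = 0, seed: int = 0
) -> SplitAssignment:
    """Pair-level shuffled k-fold split; one fold is the test set and the
    remaining pairs are split 80/20 into train/validation."""
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if not 0 <= test_fold < n_folds:
        raise ValueError(f"test_fold {test_fold} out of range for {n_folds} folds")
    n = len(ds)
    if n < n_folds:
        raise ValueError(f"{n} pairs cannot form {n_folds} folds")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [test_idx for _, test_idx in kf.split(np.arange(n))]
    test = folds[test_fold]
    rest = np.concatenate([f for i, f in enumerate(folds) if i != test_fold])
    train, val = train_test_split(rest, test_size=0.2, random_state=seed, shuffle=True)
    split = SplitAssignment(
        strategy="random",
        train=sorted(int(i) for i in train),
        val=sorted(int(i) for i in val),
        test=sorted(int(i) for i in test),
        seed=seed,
    )
    split.overlap = overlap_report(split, ds)
    return split


def blind_split(
    ds: DTDataset,
    entity_test_frac: float = 0.2,
    train_frac_of_trainval: float = 0.75,
    seed: int = 0,
) -> SplitAssignment:
    """Cold split: drugs and targets are independently partitioned
    (1−entity_test_frac)/entity_test_frac; a pair is a test pair iff both its
    drug and its target are test entities, a train-val pair iff both are
    train-val entities, and is discarded otherwise.  Train-val pairs are then
    split train_frac_of_trainval/(1−train_frac_of_trainval)."""
    rng = np.random.default_rng(seed)
    drug_ids = sorted(ds.drugs)
    target_ids = sorted(ds.targets)
    if len(drug_ids) < 2 or len(target_ids) < 2:
        raise ValueError("blind split needs at least two drugs and two targets")

    def partition(ids: list[str]) -> set[str]:
        n_test = max(1, int(round(entity_test_frac * len(ids))))
        return set(rng.choice(ids, size=n_test, replace=False))

    test_drugs = partition(drug_ids)
    test_targets = partition(target_ids)

    trainval_idx, test_idx, discarded = [], [], []
    for i, (d, t, _) in enumerate(ds.pairs):
        d_test, t_test = d in test_drugs, t in test_targets
        if d_test and t_test:
            test_idx.append(i)
        elif not d_test and not t_test:
            trainval_idx.append(i)
        else:
            discarded.append(i)
    if not test_idx or not trainval_idx:
        raise ValueError(
            "blind split produced an empty partition; try another seed or a "
            "denser dataset"
        )
    if len(trainval_idx) < 2:
        raise ValueError("too few train-val pairs to split; try another seed")
    train, val = train_test_split(
        np.asarray(trainval_idx),
        train_size=train_frac_of_trainval,
        random_state=seed,
        shuffle=True,
    )
    split = SplitAssignment(
        strategy="blind",
        train=sorted(int(i) for i in train),
        val=sorted(int(i) for i in val),
        test=sorted(int(i) for i in test_idx),
        seed=seed,
        discarded=discarded,
    )
    split.overlap = overlap_report(split, ds)
    return split


def overlap_report(split: SplitAssignment, ds: DTDataset) -> dict:
    """Entity-sharing bookkeeping between the train and test partitions."""
    def entities(indices):
        d = {ds.pairs[i][0] for i in indices}
        t = {ds.pairs[i][1] for i in indices}
        return d, t

    train_d, train_t = entities(split.train)
    test_d, test_t = entities(split.test)
    return {
        "shared_drugs": len(train_d & test_d),
        "shared_targets": len(train_t & test_t),
        "counts": {
            name: {
                "pairs": len(idx),
                "drugs": len({ds.pairs[i][0] for i in idx}),
                "targets": len({ds.pairs[i][1] for i in idx}),
            }
            for name, idx in split.partitions().items()
        },
        "discarded_pairs": len(split.discarded),
    }
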