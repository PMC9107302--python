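"""Dataset loading: benchmark-layout directories and flat affinity tables.

Two dialects are supported.  The benchmark directory layout (the
convention of the Davis/Kiba kinase benchmarks) holds

* ``ligands.json``   — insertion-ordered {drug id: SMILES}
* ``proteins.json``  — insertion-ordered {target id: sequence}
* ``affinities.csv`` — drugs × targets numeric matrix, empty cells or
  NaN marking unmeasured pairs
* optionally ``folds/train_folds.json`` (list of lists of pair indices)
  and ``folds/test_fold.json`` (list of pair indices); indices refer to
  row-major order over the non-missing cells of the full matrix

and the flat dialect is a delimited table with a header
``smiles,target_sequence,affinity``.

Kd labels in nanomolar can be mapped to pKd = 9 − log10(Kd/nM), the
−log10 molar scale on which the Davis affinities (range 5.0–10.8, with
5.0 the 10 μM assay cap) are expressed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DTIDataset", "DataLoadError", "pkd_from_nM",
           "load_benchmark_dir", "load_affinity_table", "split_dataset"]


class DataLoadError(ValueError):
    pass


@dataclass
class DTIDataset:
    """Aligned (SMILES, sequence, affinity) triples with optional folds."""

    pairs: list                       # of (smiles, sequence, float)
    drug_ids: list | None = None
    target_ids: list | None = None
    fold_of_pair: np.ndarray | None = None
    transform_applied: str = "none"
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def smiles(self) -> list:
        return [p[0] for p in self.pairs]

    @property
    def sequences(self) -> list:
        return [p[1] for p in self.pairs]

    @property
    def affinities(self) -> np.ndarray:
        return np.array([p[2] for p in self.pairs], dtype=np.float64)

    def subset(self, idx) -> "DTIDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return DTIDataset(
            pairs=[self.pairs[i] for i in idx],
            fold_of_pair=(self.fold_of_pair[idx]
                          if self.fold_of_pair is not None else None),
            transform_applied=self.transform_applied,
            meta=dict(self.meta))

    def validate(self) -> None:
        for k, (smi, seq, aff) in enumerate(self.pairs):
            if not smi or not seq:
                raise DataLoadError(f"pair {k}: missing smiles or sequence")
            if not np.isfinite(aff):
                raise DataLoadError(f"pair {k}: non-finite affinity")


def pkd_from_nM(kd_nM: float) -> float:
    """pKd = −log10(Kd in molar) = 9 − log10(Kd in nM)."""
    kd_nM = float(kd_nM)
    if kd_nM <= 0:
        raise ValueError("Kd must be positive")
    return 9.0 - float(np.log10(kd_nM))


_TRANSFORMS = {"none": lambda a: a, "pkd_from_nM": pkd_from_nM}


def _apply_transform(aff: float, transform: str) -> float:
    try:
        fn = _TRANSFORMS[transform]
    except KeyError:
        raise ValueError(f"unknown transform {transform!r}") from None
    return float(fn(aff))


def load_benchmark_dir(path, transform: str = "none") -> DTIDataset:
    """Load a benchmark-layout directory into a dataset.

    One pair per non-missing affinity cell, ordered row-major over
    (drug, target).  Fold files, when present, are translated from pair
    indices to a per-pair fold id; the test fold gets the id after the
    last train fold (recorded in ``meta["test_fold_id"]``).
    """
    path = Path(path)
    lig_path = path / "ligands.json"
    prot_path = path / "proteins.json"
    aff_path = path / "affinities.csv"
    for p in (lig_path, prot_path, aff_path):
        if not p.exists():
            raise DataLoadError(f"missing dataset file: {p.name}")
    ligands = json.loads(lig_path.read_text())
    proteins = json.loads(prot_path.read_text())
    mat = pd.read_csv(aff_path, header=None).to_numpy(dtype=np.float64)
    if mat.shape != (len(ligands), len(proteins)):
        raise DataLoadError(
            f"affinity matrix shape {mat.shape} does not match "
            f"{len(ligands)} drugs x {len(proteins)} targets")
    drug_ids = list(ligands)
    target_ids = list(proteins)
    pairs, pair_drug, pair_target = [], [], []
    for i, d in enumerate(drug_ids):
        for j, t in enumerate(target_ids):
            if np.isnan(mat[i, j]):
                continue
            pairs.append((ligands[d], proteins[t],
                          _apply_transform(mat[i, j], transform)))
            pair_drug.append(d)
            pair_target.append(t)

    fold_of_pair = None
    folds_dir = path / "folds"
    if folds_dir.exists():
        train_folds = json.loads((folds_dir / "train_folds.json").read_text())
        test_fold = json.loads((folds_dir / "test_fold.json").read_text())
        fold_of_pair = np.full(len(pairs), -1, dtype=np.intp)
        for f, idxs in enumerate(train_folds):
            for k in idxs:
                if not 0 <= k < len(pairs):
                    raise DataLoadError(f"fold index {k} out of range")
                fold_of_pair[k] = f
        test_id = len(train_folds)
        for k in test_fold:
            if not 0 <= k < len(pairs):
                raise DataLoadError(f"fold index {k} out of range")
            fold_of_pair[k] = test_id
        if np.any(fold_of_pair < 0):
            raise DataLoadError("fold files do not partition the pairs")

    ds = DTIDataset(pairs, drug_ids=pair_drug, target_ids=pair_target,
                    fold_of_pair=fold_of_pair, transform_applied=transform,
                    meta={"n_drugs": len(drug_ids),
                          "n_targets": len(target_ids),
                          "test_fold_id": (None if fold_of_pair is None
                                           else int(fold_of_pair.max()))})
    ds.validate()
    return ds


def load_affinity_table(path, transform: str = "none") -> DTIDataset:
    """Load a flat CSV/TSV with columns smiles, target_sequence, affinity."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = ("smiles", "target_sequence", "affinity")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataLoadError(f"missing column(s): {', '.join(missing)}")
    pairs = []
    for row_no, rec in enumerate(df.itertuples(index=False), start=1):
        try:
            aff = float(getattr(rec, "affinity"))
        except (TypeError, ValueError):
            raise DataLoadError(
                f"row {row_no}: unparseable affinity "
                f"{getattr(rec, 'affinity')!r}") from None
        pairs.append((getattr(rec, "smiles"), getattr(rec, "target_sequence"),
                      _apply_transform(aff, transform)))
    ds = DTIDataset(pairs, transform_applied=transform)
    ds.validate()
    return ds


def split_dataset(ds: DTIDataset, scheme: str = "random",
                  fraction: float = 0.8, seed: int = 0,
                  test_fold: int | None = None):
    """Split into (train, held-out) either by stored folds or at random.

    ``scheme="folds"`` puts the pairs of ``test_fold`` (default: the
    dataset's designated test fold) aside and trains on the rest;
    ``scheme="random"`` draws a seeded permutation and keeps ``fraction``
    of the pairs for training.
    """
    n = len(ds)
    if scheme == "folds":
        if ds.fold_of_pair is None:
            raise DataLoadError("dataset has no fold assignments")
        if test_fold is None:
            test_fold = ds.meta.get("test_fold_id")
        mask = ds.fold_of_pair == test_fold
        return ds.subset(np.flatnonzero(~mask)), ds.subset(np.flatnonzero(mask))
    if scheme == "random":
        if not 0 < fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        cut = int(round(fraction * n))
        return ds.subset(np.sort(perm[:cut])), ds.subset(np.sort(perm[cut:]))
    raise ValueError(f"unknown split scheme {scheme!r}")
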