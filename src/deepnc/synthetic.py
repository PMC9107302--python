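"""Self-contained synthetic drug/target/affinity fixtures.

Real affinity benchmarks cannot ship with the package, so this module
generates datasets with the same shape and a *known* structure:
parseable small-molecule SMILES from a seeded grammar (alkanes, branched
chains, ethers/alcohols/amines, benzene-containing scaffolds; 1–20 heavy
atoms), uniform random protein sequences over the 20-amino-acid
alphabet, and affinities that are a documented linear function of cheap
descriptors plus Gaussian noise:

    affinity(d, t) = c0 + c1·heavy_atoms(d) + c2·aromatic_fraction(d)
                        + c3·hydrophobic_fraction(t) + N(0, noise_sd)

The deterministic part is exposed (``descriptor_affinity``) so tests can
check parameter recovery and learnability.  Default coefficients place
affinities in the 5–11 range of pKd-scale kinase data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

from .data_io import DTIDataset
from .protein import AMINO_ACIDS

__all__ = ["SyntheticSpec", "generate_molecules", "generate_proteins",
           "generate_affinities", "make_dataset", "write_benchmark_dir",
           "write_csv"]

#: residues counted as hydrophobic for the target descriptor
HYDROPHOBIC = set("AVLIMFWYC")

#: default affinity coefficients (intercept, heavy atoms, aromatic
#: fraction, hydrophobic fraction) — pKd-like 5–11 output range
DEFAULT_COEFFS = (4.0, 0.25, 1.0, 2.0)


@dataclass(frozen=True)
class SyntheticSpec:
    n_drugs: int = 20
    n_targets: int = 10
    seq_len_range: tuple = (50, 200)
    noise_sd: float = 0.3
    coefficients: tuple = field(default=DEFAULT_COEFFS)
    seed: int = 0


# ----------------------------------------------------------------------
# molecules

_HETERO = ["O", "N", "S"]


def _random_chain(rng: np.random.Generator, n_heavy: int) -> str:
    """Branched carbon chain with optional heteroatom substitutions."""
    if n_heavy == 1:
        return "C"
    parts = []
    remaining = n_heavy
    while remaining > 0:
        parts.append("C")
        remaining -= 1
        if remaining >= 1 and rng.random() < 0.25:
            # short branch
            blen = int(rng.integers(1, min(3, remaining) + 1))
            branch = "C" * blen
            if rng.random() < 0.3:
                branch = rng.choice(_HETERO) + branch[1:] if blen > 1 else str(rng.choice(_HETERO))
            parts.append(f"({branch})")
            remaining -= blen
    smiles = "".join(parts)
    if rng.random() < 0.4:
        smiles += str(rng.choice(_HETERO))
    return smiles


def _random_aromatic(rng: np.random.Generator, n_extra: int) -> str:
    """Benzene scaffold with an aliphatic tail of ``n_extra`` atoms."""
    tail = "C" * max(n_extra, 0)
    if tail and rng.random() < 0.5:
        tail += str(rng.choice(["O", "N"]))
    return f"c1ccccc1{tail}"


def generate_molecules(n: int, seed: int = 0) -> list:
    """``n`` parseable SMILES with 1–20 heavy atoms, reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        if rng.random() < 0.4:
            smi = _random_aromatic(rng, int(rng.integers(0, 9)))
        else:
            smi = _random_chain(rng, int(rng.integers(1, 21)))
        mol = Chem.MolFromSmiles(smi)
        if mol is None or not 1 <= mol.GetNumAtoms() <= 20:
            continue  # grammar guard; rare
        out.append(Chem.MolToSmiles(mol))
    return out


def generate_proteins(n: int, len_range: tuple = (50, 200),
                      seed: int = 0) -> list:
    """Uniform random sequences over the 20-letter amino-acid alphabet."""
    lo, hi = len_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    seqs = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        seqs.append("".join(rng.choice(letters, size=length)))
    return seqs


# ----------------------------------------------------------------------
# affinities


def _mol_descriptors(smiles: str) -> tuple:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    n = mol.GetNumAtoms()
    aro = sum(a.GetIsAromatic() for a in mol.GetAtoms())
    return float(n), aro / n


def _hydrophobic_fraction(seq: str) -> float:
    return sum(c in HYDROPHOBIC for c in seq) / len(seq)


def descriptor_affinity(smiles: str, seq: str, coefficients=DEFAULT_COEFFS) -> float:
    """Deterministic part of the synthetic affinity function."""
    c0, c1, c2, c3 = coefficients
    heavy, arofrac = _mol_descriptors(smiles)
    return c0 + c1 * heavy + c2 * arofrac + c3 * _hydrophobic_fraction(seq)


def generate_affinities(drugs: list, targets: list,
                        spec: SyntheticSpec) -> DTIDataset:
    """Full cross of drugs × targets with noisy descriptor affinities."""
    if not drugs or not targets:
        raise ValueError("need at least one drug and one target")
    rng = np.random.default_rng(spec.seed + 1)
    pairs = []
    for smi in drugs:
        for seq in targets:
            mu = descriptor_affinity(smi, seq, spec.coefficients)
            pairs.append((smi, seq, mu + rng.normal(0.0, spec.noise_sd)))
    ds = DTIDataset(pairs, meta={"synthetic": True,
                                 "coefficients": list(spec.coefficients),
                                 "noise_sd": spec.noise_sd})
    ds.validate()
    return ds


def make_dataset(spec: SyntheticSpec) -> DTIDataset:
    """Generate molecules, proteins and affinities from one spec."""
    drugs = generate_molecules(spec.n_drugs, spec.seed)
    targets = generate_proteins(spec.n_targets, spec.seq_len_range,
                                spec.seed + 7)
    return generate_affinities(drugs, targets, spec)


# ----------------------------------------------------------------------
# writers exercising both loader dialects


def write_benchmark_dir(spec: SyntheticSpec, outdir,
                        n_train_folds: int = 5,
                        test_fraction: float = 0.2) -> Path:
    """Materialize a spec as a benchmark-layout directory with folds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    drugs = generate_molecules(spec.n_drugs, spec.seed)
    targets = generate_proteins(spec.n_targets, spec.seq_len_range,
                                spec.seed + 7)
    ds = generate_affinities(drugs, targets, spec)
    (outdir / "ligands.json").write_text(json.dumps(
        {f"drug{i}": s for i, s in enumerate(drugs)}, indent=0))
    (outdir / "proteins.json").write_text(json.dumps(
        {f"target{j}": s for j, s in enumerate(targets)}, indent=0))
    mat = ds.affinities.reshape(len(drugs), len(targets))
    np.savetxt(outdir / "affinities.csv", mat, delimiter=",", fmt="%.6f")
    n = len(ds)
    rng = np.random.default_rng(spec.seed + 13)
    perm = rng.permutation(n)
    n_test = int(round(test_fraction * n))
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    folds = [sorted(int(k) for k in train_idx[f::n_train_folds])
             for f in range(n_train_folds)]
    folds_dir = outdir / "folds"
    folds_dir.mkdir(exist_ok=True)
    (folds_dir / "train_folds.json").write_text(json.dumps(folds))
    (folds_dir / "test_fold.json").write_text(
        json.dumps([int(k) for k in test_idx]))
    return outdir


def write_csv(spec: SyntheticSpec, path) -> Path:
    """Materialize a spec as the flat table dialect."""
    path = Path(path)
    ds = make_dataset(spec)
    lines = ["smiles,target_sequence,affinity"]
    for smi, seq, aff in ds.pairs:
        lines.append(f"{smi},{seq},{aff:.6f}")
    path.write_text("\n".join(lines) + "\n")
    return path
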