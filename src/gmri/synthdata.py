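"""Synthetic data generation and dataset input/output.

The refractive-index datasets this package targets are proprietary catalog
extracts, so quantitative behavior is exercised on *teacher–student*
benchmarks: a planted graph machine (the teacher) labels randomly
generated valence-correct molecules, Gaussian measurement noise is added,
and the values are mapped into the empirical refractive-index window
(1.296–1.687).  A student model of known complexity then has a recoverable
ground truth, which is what the recovery and complexity-scan tests use.

The molecule generator grows bounded-size trees over a configurable
element alphabet with valence-respecting bond orders, occasional ring
closures and optional stereo assignment (tetrahedral tags and double-bond
E/Z).  It aims for structural variety, not chemical exhaustiveness.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from rdkit import Chem

from . import chem_graph as cg
from .curation import CompoundRecord
from .gm_core import Architecture, GraphBatch, parameter_count
from .series import SeriesModel, SeriesPoint, series_n
from .training import TrainingSet

#: Empirical range of the targeted refractive indices.
RI_WINDOW = (1.296, 1.687)

_VALENCE = {
    "C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1,
    "Si": 4, "P": 3, "B": 3,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a teacher–student dataset."""

    n_molecules: int = 200
    atom_alphabet: tuple[str, ...] = ("C", "N", "O", "F", "S", "Cl")
    max_heavy_atoms: int = 12
    ring_probability: float = 0.25
    stereo_probability: float = 0.5
    teacher_hidden: int = 4
    n_child_slots: int = 4
    noise_sd: float = 0.002
    value_window: Optional[tuple[float, float]] = RI_WINDOW
    seed: int = 0


@dataclass
class Teacher:
    """The planted ground-truth model and its output calibration."""

    arch: Architecture
    theta: np.ndarray
    scale: float
    offset: float
    smiles: list[str]
    y_clean: np.ndarray  # calibrated, noise-free values


def _grow_skeleton(rng: np.random.Generator, alphabet, n_heavy: int):
    """Carbon-backbone random tree with occasional double bonds.

    Molecules are organic-liquid-like: the seed atom is carbon and
    heteroatoms attach only to carbon (no O–F, S–S, ... linkages), so the
    generator decorates carbon skeletons with functional groups instead of
    producing exotic heteroatom clusters.
    """
    weights = np.array([4.0 if el == "C" else 1.0 for el in alphabet])
    weights /= weights.sum()
    mol = Chem.RWMol()
    free = []  # remaining valence per atom
    symbols = []
    mol.AddAtom(Chem.Atom("C"))
    free.append(_VALENCE["C"])
    symbols.append("C")
    while mol.GetNumAtoms() < n_heavy:
        open_atoms = [i for i, f in enumerate(free) if f >= 1]
        if not open_atoms:
            break
        host = int(rng.choice(open_atoms))
        el = alphabet[rng.choice(len(alphabet), p=weights)]
        if symbols[host] != "C" and el != "C":
            el = "C"  # heteroatoms bond to carbon only
        new = mol.AddAtom(Chem.Atom(el))
        order = 1
        if (
            free[host] >= 2
            and _VALENCE[el] >= 2
            and rng.random() < 0.15
        ):
            order = 2
        mol.AddBond(host, new,
                    Chem.BondType.DOUBLE if order == 2 else Chem.BondType.SINGLE)
        free[host] -= order
        free.append(_VALENCE[el] - order)
        symbols.append(el)
    return mol, free


def _close_ring(mol: Chem.RWMol, free, rng: np.random.Generator) -> None:
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(range(mol.GetNumAtoms()))
    for b in mol.GetBonds():
        G.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    dist = dict(nx.all_pairs_shortest_path_length(G))
    cands = [
        (i, j)
        for i in range(mol.GetNumAtoms())
        for j in range(i + 1, mol.GetNumAtoms())
        if free[i] >= 1
        and free[j] >= 1
        and dist[i].get(j, 99) >= 2
        and not (
            mol.GetAtomWithIdx(i).GetSymbol() != "C"
            and mol.GetAtomWithIdx(j).GetSymbol() != "C"
        )
    ]
    if not cands:
        return
    i, j = cands[int(rng.integers(len(cands)))]
    mol.AddBond(i, j, Chem.BondType.SINGLE)
    free[i] -= 1
    free[j] -= 1


def _assign_random_stereo(mol: Chem.Mol, rng: np.random.Generator) -> Chem.Mol:
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=True, useLegacyImplementation=False
    )
    for idx, code in centers:
        # only carbon centres: chiral heteroatoms are exotic in liquid-RI
        # catalogs and would appear as one-off label carriers
        if code == "?" and mol.GetAtomWithIdx(idx).GetSymbol() == "C":
            mol.GetAtomWithIdx(idx).SetChiralTag(
                Chem.ChiralType.CHI_TETRAHEDRAL_CW
                if rng.random() < 0.5
                else Chem.ChiralType.CHI_TETRAHEDRAL_CCW
            )
    Chem.FindPotentialStereoBonds(mol)
    for bond in mol.GetBonds():
        if bond.GetStereo() == Chem.BondStereo.STEREOANY:
            a = bond.GetBeginAtom()
            b = bond.GetEndAtom()
            na = [x.GetIdx() for x in a.GetNeighbors() if x.GetIdx() != b.GetIdx()]
            nb = [x.GetIdx() for x in b.GetNeighbors() if x.GetIdx() != a.GetIdx()]
            if not na or not nb:
                bond.SetStereo(Chem.BondStereo.STEREONONE)
                continue
            bond.SetStereoAtoms(na[0], nb[0])
            bond.SetStereo(
                Chem.BondStereo.STEREOZ
                if rng.random() < 0.5
                else Chem.BondStereo.STEREOE
            )
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
    return mol


def random_smiles(
    rng: np.random.Generator,
    alphabet: Sequence[str] = ("C", "N", "O", "F", "S", "Cl"),
    max_heavy_atoms: int = 12,
    ring_probability: float = 0.25,
    stereo_probability: float = 0.3,
) -> str:
    """One random valence-correct isomeric SMILES (pure in the rng state)."""
    for el in alphabet:
        if el not in _VALENCE:
            raise ValueError(f"no valence rule for element {el!r}")
    while True:
        n_heavy = int(rng.integers(2, max_heavy_atoms + 1))
        mol, free = _grow_skeleton(rng, tuple(alphabet), n_heavy)
        if rng.random() < ring_probability and mol.GetNumAtoms() >= 3:
            _close_ring(mol, free, rng)
        try:
            m = mol.GetMol()
            Chem.SanitizeMol(m)
            if rng.random() < stereo_probability:
                m = _assign_random_stereo(m, rng)
                Chem.SanitizeMol(m)
            smi = Chem.MolToSmiles(m)
            # round-trip guard: the SMILES must re-parse cleanly
            if Chem.MolFromSmiles(smi) is None:
                continue
            return smi
        except Exception:
            continue


def generate_teacher_dataset(
    cfg: SyntheticConfig,
) -> tuple[TrainingSet, Teacher]:
    """Planted-teacher dataset: random molecules scored by a random GM.

    The teacher's raw outputs are affinely mapped into ``value_window``
    (margin of five noise standard deviations so the added Gaussian noise
    rarely clips); the map is recorded on the returned :class:`Teacher` so
    recovery checks can work on the unmapped scale, where the teacher is a
    member of the student's own model family.  ``value_window=None`` skips
    the calibration (scale 1, offset 0).
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_mol, rng_theta, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )
    arch = Architecture(
        n_hidden=cfg.teacher_hidden,
        n_child_slots=cfg.n_child_slots,
        atom_alphabet=tuple(cfg.atom_alphabet),
    )
    smiles = [
        random_smiles(
            rng_mol,
            alphabet=cfg.atom_alphabet,
            max_heavy_atoms=cfg.max_heavy_atoms,
            ring_probability=cfg.ring_probability,
            stereo_probability=cfg.stereo_probability,
        )
        for _ in range(cfg.n_molecules)
    ]
    dags = [cg.smiles_to_dag(s, alphabet=cfg.atom_alphabet) for s in smiles]
    theta = rng_theta.uniform(-0.3, 0.3, parameter_count(arch))
    raw = GraphBatch(dags, arch).outputs(theta)

    if cfg.value_window is None:
        scale, offset = 1.0, 0.0
        y_clean = raw.copy()
    else:
        lo, hi = cfg.value_window
        margin = 5.0 * cfg.noise_sd
        span = raw.max() - raw.min()
        if span < 1e-12:
            scale, offset = 1.0, (lo + hi) / 2.0 - float(raw.mean())
        else:
            scale = (hi - lo - 2 * margin) / span
            offset = lo + margin - scale * raw.min()
        y_clean = scale * raw + offset
    y = y_clean + rng_noise.normal(0.0, cfg.noise_sd, size=y_clean.size)
    if cfg.value_window is not None:
        y = np.clip(y, *cfg.value_window)
    tset = TrainingSet(dags, y, arch)
    teacher = Teacher(
        arch=arch,
        theta=theta,
        scale=float(scale),
        offset=float(offset),
        smiles=smiles,
        y_clean=y_clean,
    )
    return tset, teacher


def mirror_smiles(smiles: str) -> str:
    """SMILES of the mirror image (all tetrahedral tags inverted)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"bad SMILES {smiles!r}")
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        elif tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
    return Chem.MolToSmiles(mol)


def _flip_one_center(smiles: str) -> Optional[str]:
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        tag = atom.GetChiralTag()
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
            return Chem.MolToSmiles(mol)
        if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CCW:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
            return Chem.MolToSmiles(mol)
    return None


def generate_stereo_pairs(
    n_pairs: int,
    seed: int = 0,
    alphabet: Sequence[str] = ("C", "N", "O", "F", "S", "Cl"),
    max_heavy_atoms: int = 12,
) -> list[tuple[str, str, str]]:
    """(smiles, enantiomer, diastereomer) triples with ≥2 CIP centres.

    The enantiomer inverts every tetrahedral tag, the diastereomer exactly
    one; candidates where the mirror image equals the original (meso) are
    discarded so each pair is a genuine enantiomer pair.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str, str]] = []
    attempts = 0
    while len(out) < n_pairs and attempts < 10000 * n_pairs:
        attempts += 1
        smi = random_smiles(
            rng,
            alphabet=alphabet,
            max_heavy_atoms=max_heavy_atoms,
            ring_probability=0.4,
            stereo_probability=1.0,
        )
        mol = Chem.MolFromSmiles(smi)
        centers = Chem.FindMolChiralCenters(
            mol, includeUnassigned=False, useLegacyImplementation=False
        )
        if len([c for c in centers if c[1] in ("R", "S")]) < 2:
            continue
        canon = Chem.MolToSmiles(mol)
        mirrored = mirror_smiles(canon)
        if mirrored == canon:
            continue  # meso: the mirror image is the same compound
        dia = _flip_one_center(canon)
        if dia is None or dia in (canon, mirrored):
            continue
        out.append((canon, mirrored, dia))
    if len(out) < n_pairs:
        raise RuntimeError("could not generate enough stereo pairs")
    return out


def generate_series(
    model: SeriesModel, N_max: int, noise_sd: float = 0.0, seed: int = 0
) -> list[SeriesPoint]:
    """Points (N, n(N) + noise) for N = 0..N_max."""
    rng = np.random.default_rng(seed)
    pts = []
    for N in range(N_max + 1):
        n = series_n(N, model) + (
            rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        )
        pts.append(SeriesPoint(N=N, n_obs=float(n)))
    return pts


def read_dataset(
    path: Union[str, Path],
    alphabet: Sequence[str] = cg.DEFAULT_ALPHABET,
) -> tuple[list[CompoundRecord], list[str]]:
    """Load a (smiles, ri[, temperature, id]) CSV into compound records.

    Rows whose SMILES does not parse or whose RI falls outside the 1.2–2.0
    sanity window are quarantined (status + reason), never fatal; the
    returned problem list carries one line-numbered message per bad row.
    Missing required columns raise.
    """
    df = pd.read_csv(path)
    missing = {"smiles", "ri"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset is missing columns: {sorted(missing)}")
    records: list[CompoundRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        rec = CompoundRecord(
            smiles=str(row["smiles"]),
            ri=float(row["ri"]),
            temperature=(
                float(row["temperature"])
                if "temperature" in df.columns and pd.notna(row["temperature"])
                else None
            ),
            id=str(row["id"]) if "id" in df.columns and pd.notna(row.get("id")) else "",
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", cg.UnknownElementWarning)
                cg.parse_smiles(rec.smiles, alphabet)
        except (cg.SmilesError, ValueError) as exc:
            rec.status = "quarantined"
            rec.reason = str(exc)
            problems.append(f"line {line}: {exc}")
            records.append(rec)
            continue
        if not 1.2 < rec.ri < 2.0:
            rec.status = "quarantined"
            rec.reason = f"RI {rec.ri} outside the 1.2–2.0 sanity window"
            problems.append(f"line {line}: {rec.reason}")
        records.append(rec)
    return records, problems


def write_dataset(path: Union[str, Path], records: Sequence[CompoundRecord]) -> None:
    pd.DataFrame(
        {
            "smiles": [r.smiles for r in records],
            "ri": [f"{r.ri:.3f}" for r in records],
            "temperature": [r.temperature for r in records],
            "id": [r.id for r in records],
        }
    ).to_csv(path, index=False)


def write_predictions(
    path: Union[str, Path],
    smiles: Sequence[str],
    predictions: Sequence[float],
    spread: Optional[Sequence[float]] = None,
    flags: Optional[Sequence[bool]] = None,
) -> None:
    """Prediction CSV: smiles, prediction (3 decimals), spread, flag."""
    n = len(smiles)
    pd.DataFrame(
        {
            "smiles": list(smiles),
            "prediction": [f"{p:.3f}" for p in predictions],
            "spread": list(spread) if spread is not None else [np.nan] * n,
            "flag": list(flags) if flags is not None else [False] * n,
        }
    ).to_csv(path, index=False)
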