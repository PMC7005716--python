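"""Biomolecular structures: PDB I/O, atom selection, local domains, and an
idealized DNA generator.

The generator places published standard-reference-frame base coordinates
(bundled in ``data/standard_bases.json``) by canonical Watson-Crick
geometry and then perturbs them with CEHS helical parameters, so every
downstream topological result is reproducible without external data.
Local domains (base pairs, base steps) are the units on which localized
persistent homology operates.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib.resources import files

import numpy as np

from .cehs import (
    PAIR_PARAMETER_NAMES,
    STEP_PARAMETER_NAMES,
    HelicalParams,
    HelicalParamTable,
    fit_frame,
    mid_frame,
    step_transform,
)

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

PURINES = frozenset({"A", "G"})
PYRIMIDINES = frozenset({"T", "C", "U"})
_RESTYPE_BY_RESNAME = {
    "A": "A", "DA": "A", "ADE": "A",
    "T": "T", "DT": "T", "THY": "T",
    "G": "G", "DG": "G", "GUA": "G",
    "C": "C", "DC": "C", "CYT": "C",
    "U": "U", "DU": "U", "URA": "U",
}
# atoms kept by the ``cehs-subset`` selection scheme
CEHS_PURINE_ATOMS = frozenset({"C8", "C4", "N1", "C1'"})
CEHS_PYRIMIDINE_ATOMS = frozenset({"N3", "C6", "C1'"})

with (files("lwph.data") / "standard_bases.json").open() as _fh:
    _raw = json.load(_fh)
STANDARD_BASES: dict[str, dict[str, np.ndarray]] = {
    base: {name: np.asarray(xyz, dtype=float) for name, xyz in table.items()}
    for base, table in _raw.items()
    if base != "comment"
}
del _raw

WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
# paired partner in the standard reference frame: negate y and z
_WC_FLIP = np.diag([1.0, -1.0, -1.0])


class PDBFormatError(ValueError):
    """An unparseable PDB record."""


class EmptyStructureError(ValueError):
    """A file or selection yielding zero atoms."""


class PairingError(ValueError):
    """Duplex chains that cannot be paired positionally."""


@dataclass(frozen=True)
class AtomRecord:
    """Identity of one atom; coordinates live in the owning Structure."""

    name: str
    element: str
    chain: str
    resnum: int
    icode: str = ""
    resname: str = ""

    @property
    def restype(self) -> str:
        return _RESTYPE_BY_RESNAME.get(self.resname.strip().upper(), "other")

    @property
    def residue_id(self) -> str:
        return f"{self.chain}:{self.resnum}{self.icode}".strip()


class Structure:
    """An atom roster plus one or more coordinate frames (models)."""

    def __init__(self, atoms, models):
        self.atoms = tuple(atoms)
        models = np.asarray(models, dtype=float)
        if models.ndim == 2:
            models = models[None, :, :]
        if models.ndim != 3 or models.shape[2] != 3:
            raise ValueError(f"models must have shape (M, N, 3), got {models.shape}")
        if models.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate count {models.shape[1]} != atom count {len(self.atoms)}"
            )
        if not np.all(np.isfinite(models)):
            raise ValueError("coordinates must be finite")
        for a in self.atoms:
            if not a.residue_id or a.residue_id == ":":
                raise ValueError("residue identifiers must be non-empty")
        self.models = models

    # -- basic accessors ----------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_models(self) -> int:
        return self.models.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """Coordinates of the first model, shape (N, 3)."""
        return self.models[0]

    @property
    def residue_ids(self) -> list[str]:
        return [a.residue_id for a in self.atoms]

    def residues(self) -> list[str]:
        """Unique residue identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def subset(self, indices) -> "Structure":
        indices = list(indices)
        return Structure([self.atoms[i] for i in indices], self.models[:, indices, :])

    def model(self, m: int) -> "Structure":
        return Structure(self.atoms, self.models[m][None, :, :])

    def frames(self):
        for m in range(self.n_models):
            yield self.model(m)

    def __len__(self) -> int:
        return self.n_atoms

    def __repr__(self) -> str:
        return (
            f"<Structure {self.n_atoms} atoms, {len(self.residues())} residues, "
            f"{self.n_models} model(s)>"
        )


@dataclass(frozen=True)
class LocalDomain:
    """A labelled set of atom indices into a Structure (domains may overlap)."""

    label: str
    atom_indices: tuple[int, ...]
    residues: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("domain atom indices must be unique")


# ---------------------------------------------------------------------------
# PDB I/O (reading through Biopython, writing fixed-width records)
# ---------------------------------------------------------------------------


def _first_malformed_line(path) -> int | None:
    """Line number of the first ATOM/HETATM record with broken fixed columns."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.startswith(("ATOM", "HETATM")):
                    continue
                try:
                    int(line[6:11])
                    int(line[22:26])
                    for span in ((30, 38), (38, 46), (46, 54)):
                        float(line[span[0] : span[1]])
                except (ValueError, IndexError):
                    return lineno
    except OSError:
        return None
    return None


def read_pdb(path, include_hydrogens: bool = False) -> Structure:
    """Read a (possibly multi-model) PDB file into a Structure.

    Heavy atoms only unless ``include_hydrogens``; for alternate
    locations the first-listed altLoc is kept; every MODEL must share
    the same atom roster.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bio = parser.get_structure("s", str(path))
    except (PDBConstructionException, ValueError) as exc:
        lineno = _first_malformed_line(path)
        where = f" at line {lineno}" if lineno else ""
        raise PDBFormatError(f"unparseable PDB record in {path}{where}: {exc}") from exc

    rosters, model_coords = [], []
    for model in bio:
        atoms, coords = [], []
        for chain in model:
            for residue in chain:
                seen_names: set[str] = set()
                for atom in residue.get_unpacked_list():
                    if atom.get_name() in seen_names:
                        continue  # later altLoc of an atom already kept
                    seen_names.add(atom.get_name())
                    element = (atom.element or "").strip().upper()
                    if not include_hydrogens and element in {"H", "D"}:
                        continue
                    atoms.append(
                        AtomRecord(
                            name=atom.get_name(),
                            element=element,
                            chain=chain.id if chain.id.strip() else "_",
                            resnum=residue.id[1],
                            icode=residue.id[2].strip(),
                            resname=residue.get_resname().strip(),
                        )
                    )
                    coords.append(atom.get_coord())
        rosters.append(atoms)
        model_coords.append(np.asarray(coords, dtype=float))

    if not rosters or not rosters[0]:
        raise EmptyStructureError(f"no atoms found in {path}")
    first = rosters[0]
    for i, roster in enumerate(rosters[1:], start=2):
        if roster != first:
            raise PDBFormatError(f"MODEL {i} in {path} has a different atom roster")
    return Structure(first, np.stack(model_coords))


def write_pdb(structure: Structure, path) -> None:
    """Write ATOM records (with MODEL/ENDMDL framing for multi-model input)."""
    multi = structure.n_models > 1
    with open(path, "w") as fh:
        for m in range(structure.n_models):
            if multi:
                fh.write(f"MODEL     {m + 1:4d}\n")
            for serial, (atom, xyz) in enumerate(
                zip(structure.atoms, structure.models[m]), start=1
            ):
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s} {atom.resname:>3s} "
                    f"{atom.chain[:1]}{atom.resnum:4d}{atom.icode or ' ':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------

SELECTION_SCHEMES = ("all-heavy", "base+C1'", "cehs-subset")


def select_atoms(structure: Structure, scheme: str = "base+C1'") -> Structure:
    """Restrict a structure to one of the named atom schemes.

    ``all-heavy`` keeps every non-hydrogen atom; ``base+C1'`` keeps the
    base ring/heavy atoms plus the C1' sugar link of each nucleotide;
    ``cehs-subset`` keeps {C8, C4, N1, C1'} for purines and {N3, C6,
    C1'} for pyrimidines.  Nucleotides missing a required named atom are
    skipped with a warning.
    """
    if scheme not in SELECTION_SCHEMES:
        raise ValueError(f"unknown selection scheme {scheme!r}; expected one of {SELECTION_SCHEMES}")
    if scheme == "all-heavy":
        keep = [i for i, a in enumerate(structure.atoms) if a.element not in {"H", "D"}]
        return structure.subset(keep)

    keep: list[int] = []
    by_residue: dict[str, list[int]] = {}
    for i, a in enumerate(structure.atoms):
        by_residue.setdefault(a.residue_id, []).append(i)
    for rid, indices in by_residue.items():
        restype = structure.atoms[indices[0]].restype
        if restype == "other":
            logger.warning("residue %s is not a standard nucleotide; skipped", rid)
            continue
        if scheme == "base+C1'":
            wanted = set(STANDARD_BASES[restype])
        else:
            wanted = CEHS_PURINE_ATOMS if restype in PURINES else CEHS_PYRIMIDINE_ATOMS
        found = [i for i in indices if structure.atoms[i].name in wanted]
        names = {structure.atoms[i].name for i in found}
        if names != set(wanted):
            warnings.warn(
                f"residue {rid} misses atoms {sorted(set(wanted) - names)}; skipped",
                stacklevel=2,
            )
            continue
        keep.extend(found)
    if not keep:
        raise EmptyStructureError(f"selection {scheme!r} matched no atoms")
    return structure.subset(keep)


# ---------------------------------------------------------------------------
# idealized DNA generator
# ---------------------------------------------------------------------------


def _parse_pair_type(pair_type: str) -> tuple[str, str]:
    try:
        first, second = pair_type.split("-")
    except ValueError:
        raise ValueError(f"pair type must look like 'A-T', got {pair_type!r}") from None
    first, second = first.strip().upper(), second.strip().upper()
    if WC_COMPLEMENT.get(first) != second:
        raise ValueError(f"{pair_type!r} is not a Watson-Crick pair")
    return first, second


def _nucleotide_atoms(base: str, chain: str, resnum: int):
    table = STANDARD_BASES[base]
    records = [
        AtomRecord(name=name, element=name[0], chain=chain, resnum=resnum, resname=f"D{base}")
        for name in table
    ]
    coords = np.array([table[name] for name in table])
    return records, coords


def _pair_coords(base1: str, base2: str, pair_params: np.ndarray):
    """Both nucleotides of one pair, in pair (mid-frame) coordinates.

    The six base-pair parameters (shear, stretch, stagger, buckle,
    propeller, opening) describe base 1 relative to the y/z-flipped
    frame of base 2, so positive stretch pulls the bases apart along the
    pair y axis; both bases sit half the transform away from the pair
    mid-frame, and zero parameters give the canonical WC pair.
    """
    t = np.asarray(pair_params[:3], dtype=float)
    R2, _, Rm = step_transform(t, pair_params[3:6])
    s1 = STANDARD_BASES[base1]
    s2 = STANDARD_BASES[base2]
    coords1 = np.stack([Rm.T @ R2 @ s1[name] + t / 2.0 for name in s1])
    coords2 = np.stack([Rm.T @ (_WC_FLIP @ s2[name]) - t / 2.0 for name in s2])
    return coords1, coords2


def build_base_pair(
    pair_type: str = "A-T", params: HelicalParams | None = None, chain_ids=("A", "B")
) -> Structure:
    """One idealized Watson-Crick base pair (base heavy atoms + C1').

    With zero parameters the minimum inter-base heavy-atom distance sits
    in the hydrogen-bond window (2.7-3.0 Angstrom).
    """
    params = params or HelicalParams()
    base1, base2 = _parse_pair_type(pair_type)
    coords1, coords2 = _pair_coords(base1, base2, params.pair_part)
    rec1, _ = _nucleotide_atoms(base1, chain_ids[0], 1)
    rec2, _ = _nucleotide_atoms(base2, chain_ids[1], 1)
    return Structure(rec1 + rec2, np.vstack([coords1, coords2]))


def _normalize_step_type(step_type) -> tuple[str, str]:
    """Accept a strand-I dimer string ('AT') or two pair types ('A-T', 'T-A')."""
    if isinstance(step_type, str) and "-" not in step_type:
        if len(step_type) != 2 or any(b not in WC_COMPLEMENT for b in step_type.upper()):
            raise ValueError(f"step type {step_type!r} is not a two-letter DNA dimer")
        s = step_type.upper()
        return (f"{s[0]}-{WC_COMPLEMENT[s[0]]}", f"{s[1]}-{WC_COMPLEMENT[s[1]]}")
    pair1, pair2 = step_type
    _parse_pair_type(pair1), _parse_pair_type(pair2)
    return pair1, pair2


def build_base_step(step_type="AT", params: HelicalParams | None = None) -> Structure:
    """Two stacked base pairs related by the CEHS mid-step transform.

    The step part of ``params`` (shift, slide, rise, tilt, roll, twist)
    places pair 2 relative to pair 1; the pair part is applied to both
    pairs.
    """
    params = params or HelicalParams()
    pair1, pair2 = _normalize_step_type(step_type)
    seq = pair1.split("-")[0] + pair2.split("-")[0]
    return build_duplex(seq, step_params=params, pair_params=params)


def build_duplex(
    sequence: str,
    step_params: HelicalParams | list[HelicalParams] | None = None,
    pair_params: HelicalParams | list[HelicalParams] | None = None,
    chain_ids=("A", "B"),
) -> Structure:
    """An idealized duplex from the strand-I sequence (5'->3').

    ``step_params`` (one set, or one per step) stacks consecutive pairs;
    ``pair_params`` perturbs each pair internally.  Chain 2 residue
    numbers run so that chain-1 residue i pairs chain-2 residue L-i+1.
    """
    sequence = sequence.upper()
    L = len(sequence)
    if L < 1 or any(b not in WC_COMPLEMENT for b in sequence):
        raise ValueError(f"invalid DNA sequence {sequence!r}")
    n_steps = L - 1

    def _broadcast(p, n, default):
        if p is None:
            return [default] * n
        if isinstance(p, HelicalParams):
            return [p] * n
        p = list(p)
        if len(p) != n:
            raise ValueError(f"expected {n} parameter sets, got {len(p)}")
        return p

    zero = HelicalParams()
    steps = _broadcast(step_params, n_steps, zero)
    pairs = _broadcast(pair_params, L, zero)

    R = np.eye(3)
    origin = np.zeros(3)
    per_residue: dict[tuple[str, int], tuple[list[AtomRecord], np.ndarray]] = {}
    for i, base in enumerate(sequence):
        comp = WC_COMPLEMENT[base]
        c1, c2 = _pair_coords(base, comp, pairs[i].pair_part)
        rec1, _ = _nucleotide_atoms(base, chain_ids[0], i + 1)
        rec2, _ = _nucleotide_atoms(comp, chain_ids[1], L - i)
        per_residue[(chain_ids[0], i + 1)] = (rec1, (R @ c1.T).T + origin)
        per_residue[(chain_ids[1], L - i)] = (rec2, (R @ c2.T).T + origin)
        if i < n_steps:
            sp = steps[i].step_part
            R2, o2, _ = step_transform(sp[:3], sp[3:6])
            origin = origin + R @ o2
            R = R @ R2
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    for chain in chain_ids:
        for resnum in sorted(r for c, r in per_residue if c == chain):
            rec, xyz = per_residue[(chain, resnum)]
            atoms.extend(rec)
            coords.append(xyz)
    return Structure(atoms, np.vstack(coords))


# ---------------------------------------------------------------------------
# local domains
# ---------------------------------------------------------------------------


def paired_residues(duplex: Structure) -> list[tuple[str, str]]:
    """Positional Watson-Crick pairing: chain-1 residue i with chain-2 residue L-i+1."""
    chains: dict[str, list[str]] = {}
    for a in duplex.atoms:
        lst = chains.setdefault(a.chain, [])
        if a.residue_id not in lst:
            lst.append(a.residue_id)
    if len(chains) != 2:
        raise PairingError(f"expected 2 chains, found {sorted(chains)}")
    (c1, r1), (c2, r2) = sorted(chains.items())
    if len(r1) != len(r2):
        raise PairingError(f"chains {c1} and {c2} have unequal lengths {len(r1)} != {len(r2)}")
    return [(r1[i], r2[len(r2) - 1 - i]) for i in range(len(r1))]


def enumerate_local_domains(
    duplex: Structure, window: str = "base-step", exclude_terminal: bool = True
) -> list[LocalDomain]:
    """Decompose a duplex into overlapping base-pair or base-step domains.

    Base-step windows cover consecutive pair indices (i, i+1) and
    overlap by one pair; ``exclude_terminal`` drops the first and last
    window.  An n-mer duplex yields n-1 steps (n-3 non-terminal).
    """
    if window not in ("base-pair", "base-step"):
        raise ValueError(f"unknown window {window!r}")
    pairs = paired_residues(duplex)
    index_of: dict[str, list[int]] = {}
    for i, a in enumerate(duplex.atoms):
        index_of.setdefault(a.residue_id, []).append(i)

    if window == "base-pair":
        groups = [((i + 1,), p) for i, p in enumerate(pairs)]
    else:
        groups = [
            ((i + 1, i + 2), (*pairs[i], *pairs[i + 1])) for i in range(len(pairs) - 1)
        ]
    if exclude_terminal:
        groups = groups[1:-1] if len(groups) > 2 else []
    domains = []
    for pair_idx, residues in groups:
        indices = [j for rid in residues for j in index_of[rid]]
        tag = "pair" if window == "base-pair" else "step"
        label = f"{tag}_{'-'.join(str(i) for i in pair_idx)}"
        domains.append(LocalDomain(label, tuple(indices), tuple(residues)))
    return domains


def domains_to_json(domains: list[LocalDomain]) -> str:
    return json.dumps(
        [
            {"label": d.label, "atom_indices": list(d.atom_indices), "residues": list(d.residues)}
            for d in domains
        ],
        indent=1,
    )


# ---------------------------------------------------------------------------
# parameter sweeps
# ---------------------------------------------------------------------------


def sweep_helical_parameter(
    table: HelicalParamTable | None = None,
    index: str = "rise",
    n: int = 11,
    step_type="AT",
) -> list[Structure]:
    """n base-step structures with parameter ``index`` spanning mean +/- 2 SD.

    The swept parameter takes n equally spaced values on
    [mean - 2 sd, mean + 2 sd] inclusive; all other parameters stay at
    their table means.
    """
    table = table or HelicalParamTable.default()
    if index not in PAIR_PARAMETER_NAMES + STEP_PARAMETER_NAMES:
        raise ValueError(f"unknown helical parameter {index!r}")
    if n < 2:
        raise ValueError("need n >= 2 sweep points")
    mu, sd = table.means[index], table.sds[index]
    if sd == 0:
        warnings.warn(f"sd of {index!r} is zero: all sweep structures identical", stacklevel=2)
    base = table.mean_params()
    values = np.linspace(mu - 2 * sd, mu + 2 * sd, n)
    return [build_base_step(step_type, base.with_(**{index: float(v)})) for v in values]


# ---------------------------------------------------------------------------
# CEHS analysis (the builders' geometric inverse)
# ---------------------------------------------------------------------------


def _residue_frame(structure: Structure, rid: str, strand2: bool):
    """Fit the base reference frame of one residue by Kabsch superposition."""
    idx = [i for i, a in enumerate(structure.atoms) if a.residue_id == rid]
    restype = structure.atoms[idx[0]].restype
    table = STANDARD_BASES[restype]
    names = [structure.atoms[i].name for i in idx if structure.atoms[i].name in table]
    if len(names) < 3:
        raise ValueError(f"residue {rid}: too few reference atoms to fit a frame")
    template = np.stack([table[n] for n in names])
    if strand2:
        template = template @ _WC_FLIP.T
    observed = np.stack(
        [structure.coords[i] for i in idx if structure.atoms[i].name in table]
    )
    return fit_frame(template, observed)


def _pair_frame(structure: Structure, rid1: str, rid2: str):
    """Mid-frame of base 1 and the flipped base 2, plus the parameters of
    base 1 relative to flipped base 2 (the builder's convention)."""
    R1, o1 = _residue_frame(structure, rid1, strand2=False)
    R2, o2 = _residue_frame(structure, rid2, strand2=True)
    Rm, om, p = mid_frame(R2, o2, R1, o1)
    return Rm, om, p


def pair_parameters(structure: Structure) -> HelicalParams:
    """Recover (shear..opening) of a two-residue base pair."""
    pairs = paired_residues(structure)
    if len(pairs) != 1:
        raise ValueError("pair_parameters expects a single base pair")
    _, _, (d1, d2, d3, tilt, roll, twist) = _pair_frame(structure, *pairs[0])
    return HelicalParams(
        shear=d1, stretch=d2, stagger=d3, buckle=tilt, propeller=roll, opening=twist
    )


def step_parameters(structure: Structure, step_index: int = 0) -> HelicalParams:
    """Recover (shift..twist) between consecutive pairs of a duplex."""
    pairs = paired_residues(structure)
    if len(pairs) < 2:
        raise ValueError("step_parameters needs at least two base pairs")
    Ra, oa, _ = _pair_frame(structure, *pairs[step_index])
    Rb, ob, _ = _pair_frame(structure, *pairs[step_index + 1])
    _, _, (d1, d2, d3, tilt, roll, twist) = mid_frame(Ra, oa, Rb, ob)
    return HelicalParams(shift=d1, slide=d2, rise=d3, tilt=tilt, roll=roll, twist=twist)
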