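"""File formats and run configuration.

Structures travel as PDB/GRO (via biotite, coordinates normalized to nm
internally), kinetic traces as columnar CSV with header
``time_ns,dz_nm,theta_deg`` (one file per trajectory, or long format with
a ``trajectory_id`` column), umbrella windows as one CSV per window plus
a JSON manifest, and the run configuration as one declarative YAML
document that round-trips losslessly and hashes stably.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .contacts import ContactPolicy
from .kinetics import KineticTrace
from .pmf import GridSpec, UmbrellaWindow, UmbrellaWindowSet
from .synthetic import (BilayerModel, LangevinConfig, LipidPseudo, PeptideModel,
                        _POLARITY, _RESIDUE_NAMES, assign_fragments)


class StructureError(ValueError):
    """A structure file cannot be mapped onto the expected models."""


_NAME_TO_CODE = {v: k for k, v in _RESIDUE_NAMES.items()}
_DEFAULT_LIPID_RESNAMES = ("LIP", "POPC")
_DEFAULT_HEAD_NAMES = ("P", "N")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Declarative document of every tunable in the pipeline."""

    chirality: str = "L"
    seed: int = 0
    fpt_threshold: float = 1.5  # nm
    band_width: float = 100.0  # deg, surface-fragment angular band
    estimator: str = "mbar"
    k_bias: float = 1000.0  # kJ/mol/nm^2
    n_windows: int = 16
    dz_range: tuple = (1.0, 2.5)
    discard_fraction: float = 0.1
    subsample: bool = True
    tl_bin_width: float = 0.05
    lipid_resnames: tuple = _DEFAULT_LIPID_RESNAMES
    head_atom_names: tuple = _DEFAULT_HEAD_NAMES
    contact: ContactPolicy = field(default_factory=ContactPolicy)
    langevin: LangevinConfig = field(default_factory=LangevinConfig)
    grid: GridSpec = field(default_factory=GridSpec)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dz_range"] = list(self.dz_range)
        d["lipid_resnames"] = list(self.lipid_resnames)
        d["head_atom_names"] = list(self.head_atom_names)
        d["contact"]["weights"] = list(self.contact.weights)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        contact = dict(d.pop("contact", {}))
        if "weights" in contact:
            contact["weights"] = tuple(contact["weights"])
        langevin = dict(d.pop("langevin", {}))
        grid = dict(d.pop("grid", {}))
        for key in ("dz_range", "lipid_resnames", "head_atom_names"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(contact=ContactPolicy(**contact),
                   langevin=LangevinConfig(**langevin),
                   grid=GridSpec(**grid), **d)

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def save_config(config: RunConfig, path):
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# structures


def _models_to_atom_array(peptide: PeptideModel | None,
                          bilayer: BilayerModel | None):
    import biotite.structure as struc

    entries = []  # (chain, res_id, res_name, atom_name, element, xyz_nm)
    if peptide is not None:
        for name, res, elem, xyz in zip(peptide.atom_names, peptide.atom_residues,
                                        peptide.elements, peptide.coords):
            entries.append(("A", int(res), peptide.residue_name(int(res)),
                            name, elem, xyz))
    if bilayer is not None:
        for lipid in bilayer.lipids:
            rid = int(lipid.lipid_id) + 1
            for i, xyz in enumerate(np.atleast_2d(lipid.head_atoms)):
                entries.append(("L", rid, "LIP", _DEFAULT_HEAD_NAMES[i % 2],
                                _DEFAULT_HEAD_NAMES[i % 2], xyz))
            entries.append(("L", rid, "LIP", "C2", "C", lipid.c2_atom))
            for i, xyz in enumerate(np.atleast_2d(lipid.tail_atoms)):
                entries.append(("L", rid, "LIP", f"CT{i + 1}", "C", xyz))

    arr = struc.AtomArray(len(entries))
    arr.coord = np.array([e[5] for e in entries], dtype=float) * 10.0  # nm -> A
    arr.chain_id = np.array([e[0] for e in entries])
    arr.res_id = np.array([e[1] for e in entries])
    arr.res_name = np.array([e[2] for e in entries])
    arr.atom_name = np.array([e[3] for e in entries])
    arr.element = np.array([e[4] for e in entries])
    arr.hetero = np.array([e[0] == "L" for e in entries])
    if bilayer is not None:
        arr.box = np.diag(np.asarray(bilayer.box, dtype=float) * 10.0)
    return arr


def write_structure(path, peptide: PeptideModel | None = None,
                    bilayer: BilayerModel | None = None):
    """Write peptide and/or bilayer models as PDB or GRO (by extension)."""
    from biotite.structure.io.gro import GROFile
    from biotite.structure.io.pdb import PDBFile

    arr = _models_to_atom_array(peptide, bilayer)
    path = Path(path)
    if path.suffix.lower() == ".gro":
        f = GROFile()
        f.set_structure(arr)
    elif path.suffix.lower() == ".pdb":
        f = PDBFile()
        f.set_structure(arr)
    else:
        raise StructureError(f"unsupported structure format: {path.suffix}")
    f.write(str(path))


def read_structure(path, chirality: str = "L",
                   lipid_resnames=_DEFAULT_LIPID_RESNAMES,
                   head_atom_names=_DEFAULT_HEAD_NAMES):
    """Read a PDB/GRO file into (PeptideModel | None, BilayerModel | None).

    Peptide residues are recognized by name (ARG/LEU/TRP); lipid residues
    by ``lipid_resnames``, with head atoms named per ``head_atom_names``,
    a mandatory chiral C2 atom, and all remaining heavy atoms as tails.
    Coordinates are converted to nm.  The file format carries no
    handedness tag, so the enantiomer label is supplied by the caller.
    """
    from biotite.structure.io.gro import GROFile
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if path.suffix.lower() == ".gro":
        arr = GROFile.read(str(path)).get_structure(model=1)
    elif path.suffix.lower() == ".pdb":
        arr = PDBFile.read(str(path)).get_structure(model=1)
    else:
        raise StructureError(f"unsupported structure format: {path.suffix}")

    coords_nm = np.asarray(arr.coord, dtype=float) / 10.0
    res_names = np.asarray(arr.res_name)
    known_pep = set(_NAME_TO_CODE)
    lipid_set = set(lipid_resnames)
    unknown = sorted(set(res_names) - known_pep - lipid_set)
    if unknown:
        raise StructureError(f"unknown residue names: {unknown}")

    peptide = None
    pep_mask = np.isin(res_names, sorted(known_pep))
    if pep_mask.any():
        res_ids = np.asarray(arr.res_id)[pep_mask]
        order = np.argsort(res_ids, kind="stable")
        uniq = sorted(set(int(r) for r in res_ids))
        remap = {r: i + 1 for i, r in enumerate(uniq)}
        sequence = "".join(
            _NAME_TO_CODE[str(res_names[pep_mask][res_ids == r][0])] for r in uniq)
        names = [str(n) for n in np.asarray(arr.atom_name)[pep_mask][order]]
        residues = np.array([remap[int(r)] for r in res_ids[order]])
        elements = [str(e) for e in np.asarray(arr.element)[pep_mask][order]]
        coords = coords_nm[pep_mask][order]
        trp = [i for i, c in enumerate(sequence, 1) if c == "W"]
        trp_index = trp[0] if len(trp) == 1 else None
        if trp_index is not None:
            have = {n for n, r in zip(names, residues) if r == trp_index}
            if not {"CD1", "CH2"} <= have:
                warnings.warn("Trp atoms CD1/CH2 missing; Trp orientation "
                              "statistics are disabled for this structure")
        peptide = PeptideModel(
            sequence=sequence, chirality=chirality, atom_names=names,
            atom_residues=residues, elements=elements, coords=coords,
            polarity_class={i + 1: _POLARITY[c] for i, c in enumerate(sequence)},
            trp_index=trp_index, fragment_assignment=assign_fragments(sequence))

    bilayer = None
    lip_mask = np.isin(res_names, sorted(lipid_set))
    if lip_mask.any():
        res_ids = np.asarray(arr.res_id)[lip_mask]
        names = np.asarray(arr.atom_name)[lip_mask]
        coords = coords_nm[lip_mask]
        mid_z = coords[:, 2].mean()
        lipids = []
        for rid in sorted(set(int(r) for r in res_ids)):
            sel = res_ids == rid
            lnames, lcoords = names[sel], coords[sel]
            heads = lcoords[np.isin(lnames, head_atom_names)]
            c2 = lcoords[lnames == "C2"]
            tails = lcoords[~np.isin(lnames, (*head_atom_names, "C2"))]
            if c2.shape[0] != 1:
                raise StructureError(f"lipid {rid} lacks exactly one C2 atom")
            if heads.size == 0:
                raise StructureError(f"lipid {rid} has no head atoms "
                                     f"({head_atom_names})")
            lipids.append(LipidPseudo(
                lipid_id=rid - 1, head_atoms=heads, c2_atom=c2[0],
                tail_atoms=tails,
                leaflet="upper" if c2[0, 2] >= mid_z else "lower"))
        box = np.array([6.0, 6.0, 6.0])
        if arr.box is not None:
            box = np.diag(np.asarray(arr.box, dtype=float)) / 10.0
        bilayer = BilayerModel(lipids=lipids, box=box)
    return peptide, bilayer


# ---------------------------------------------------------------------------
# kinetic traces


_TRACE_COLUMNS = ["time_ns", "dz_nm", "theta_deg"]


def write_traces(traces: list, path):
    """Write traces as CSV: long format (single .csv) or one file per trace."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frames = []
        for tr in traces:
            frames.append(pd.DataFrame({
                "trajectory_id": tr.trajectory_id, "time_ns": tr.time,
                "dz_nm": tr.dz,
                "theta_deg": tr.theta if tr.theta is not None else np.nan}))
        pd.concat(frames, ignore_index=True).to_csv(
            path, index=False, float_format="%.10g", lineterminator="\n")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for tr in traces:
            pd.DataFrame({
                "time_ns": tr.time, "dz_nm": tr.dz,
                "theta_deg": tr.theta if tr.theta is not None else np.nan,
            }).to_csv(path / f"{tr.trajectory_id}.csv", index=False,
                      float_format="%.10g", lineterminator="\n")


def _trace_from_frame(df: pd.DataFrame, trajectory_id: str) -> KineticTrace:
    for col in _TRACE_COLUMNS[:2]:
        if col not in df.columns:
            raise StructureError(f"trace file lacks column {col!r}")
    theta = df["theta_deg"].to_numpy(dtype=float) if "theta_deg" in df else None
    return KineticTrace(time=df["time_ns"].to_numpy(dtype=float),
                        dz=df["dz_nm"].to_numpy(dtype=float),
                        theta=theta, trajectory_id=trajectory_id)


def read_traces(path) -> list:
    """Read kinetic traces from a CSV file or a directory of CSV files.

    A ``trajectory_id`` column splits long-format files into separate
    traces.  Time must be strictly increasing within each trace; a
    duplicated or decreasing timestamp is rejected with its row number.
    """
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    if not files:
        raise StructureError(f"no trace files found under {path}")
    traces = []
    for f in files:
        df = pd.read_csv(f)
        if "trajectory_id" in df.columns:
            for tid, sub in df.groupby("trajectory_id", sort=True):
                traces.append(_trace_from_frame(sub.reset_index(drop=True), str(tid)))
        else:
            traces.append(_trace_from_frame(df, f.stem))
    return traces


# ---------------------------------------------------------------------------
# umbrella windows


def write_umbrella(windows: UmbrellaWindowSet, outdir):
    """One CSV per window plus a JSON manifest (centers, bias, seeds)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"temperature_K": windows.temperature,
                "centers_nm": [w.center for w in windows.windows],
                "k_bias_kJ_mol_nm2": [w.k_bias for w in windows.windows],
                "seeds": [w.seed for w in windows.windows],
                "burn_in": [w.burn_in for w in windows.windows],
                "observables": sorted(set().union(
                    *(set(w.observables) for w in windows.windows)))}
    (outdir / "windows.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    for i, w in enumerate(windows.windows, start=1):
        data = {"dz_nm": w.dz}
        if w.theta is not None:
            data["theta_deg"] = w.theta
        for name, vals in sorted(w.observables.items()):
            data[name] = np.asarray(vals)
        pd.DataFrame(data).to_csv(outdir / f"window_{i:02d}.csv", index=False,
                                  float_format="%.10g", lineterminator="\n")


def read_umbrella(indir) -> UmbrellaWindowSet:
    indir = Path(indir)
    manifest = json.loads((indir / "windows.json").read_text())
    windows = []
    for i, center in enumerate(manifest["centers_nm"], start=1):
        df = pd.read_csv(indir / f"window_{i:02d}.csv")
        obs_cols = [c for c in df.columns if c not in ("dz_nm", "theta_deg")]
        windows.append(UmbrellaWindow(
            center=float(center),
            k_bias=float(manifest["k_bias_kJ_mol_nm2"][i - 1]),
            dz=df["dz_nm"].to_numpy(dtype=float),
            theta=(df["theta_deg"].to_numpy(dtype=float)
                   if "theta_deg" in df else None),
            observables={c: df[c].to_numpy(dtype=float) for c in obs_cols},
            seed=manifest["seeds"][i - 1], burn_in=manifest["burn_in"][i - 1]))
    return UmbrellaWindowSet(windows=windows,
                             temperature=float(manifest["temperature_K"]))
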