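"""Reading and writing ensemble files, peak lists, spectra and geometries.

Three disk formats are supported:

* **Ensemble**: a structured YAML document (``schema: 1``) carrying conformer
  ids, the shared solvent, total electronic energies in Hartree and the
  optional geometry / shielding / transition blocks.  The schema is designed
  so every printed table of a typical conformer study can be typed in by hand.
* **Geometry**: standard XYZ (atom count, comment line with the conformer id,
  then ``element x y z`` in Å).
* **Peak lists and spectra**: CSV with a header row.

The printed reference tables of the coumarin–cytisine conformer study ship as
packaged CSV fixtures and are exposed through the ``load_*`` helpers.
"""

from __future__ import annotations

import logging
import math
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AtomSite,
    ConformerRecord,
    Ensemble,
    ExperimentalPeak,
    ShieldingTensor,
    Spectrum,
    Transition,
    ValidationError,
)

__all__ = [
    "EnsembleFormatError",
    "read_ensemble",
    "write_ensemble",
    "read_xyz",
    "write_xyz",
    "read_peak_list",
    "write_peak_list",
    "read_spectrum",
    "write_spectrum",
    "load_energies",
    "load_carbon_shifts",
    "load_proton_shifts",
    "load_transitions",
    "load_nbo_occupancies",
    "tms_references",
    "reference_ensemble",
    "theoretical_shift_map",
    "experimental_peaks",
]

logger = logging.getLogger("confspect")

SCHEMA_VERSION = 1

# printed ranges use either a hyphen or an en dash
_RANGE_RE = re.compile(r"^\s*(-?\d+\.?\d*)\s*[-–]\s*(-?\d+\.?\d*)\s*$")


class EnsembleFormatError(ValueError):
    """Raised when an ensemble document does not conform to the schema."""


# ---------------------------------------------------------------------------
# Ensemble YAML
# ---------------------------------------------------------------------------

def _parse_transition(raw: dict, conformer_id) -> Transition:
    try:
        return Transition(
            state_index=int(raw["state"]),
            energy_ev=float(raw["energy_ev"]),
            oscillator_strength=float(raw["oscillator_strength"]),
            wavelength_nm=(
                float(raw["wavelength_nm"]) if "wavelength_nm" in raw else None
            ),
            contributions=tuple(
                (str(k), float(v)) for k, v in raw.get("contributions", [])
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise EnsembleFormatError(
            f"conformer {conformer_id}: malformed transition {raw!r}: {exc}"
        ) from exc


def _parse_conformer(raw: dict) -> ConformerRecord:
    if not isinstance(raw, dict) or "id" not in raw:
        raise EnsembleFormatError(f"malformed conformer record: {raw!r}")
    cid = raw["id"]
    try:
        energy = float(raw["total_energy_ha"])
    except (KeyError, TypeError, ValueError) as exc:
        raise EnsembleFormatError(
            f"conformer {cid}: missing or non-numeric total_energy_ha"
        ) from exc

    geometry = []
    for entry in raw.get("geometry", []):
        try:
            index, element, x, y, z = entry
            geometry.append(
                AtomSite(int(index), str(element), (float(x), float(y), float(z)))
            )
        except (TypeError, ValueError, ValidationError) as exc:
            raise EnsembleFormatError(
                f"conformer {cid}: malformed geometry entry {entry!r}: {exc}"
            ) from exc

    shieldings = []
    for entry in raw.get("shieldings", []):
        try:
            shieldings.append(
                ShieldingTensor(
                    atom_index=int(entry["atom"]),
                    components=np.asarray(entry["components"], dtype=float),
                )
            )
        except (KeyError, TypeError, ValueError, ValidationError) as exc:
            raise EnsembleFormatError(
                f"conformer {cid}: malformed shielding entry: {exc}"
            ) from exc

    transitions = [_parse_transition(t, cid) for t in raw.get("transitions", [])]

    try:
        return ConformerRecord(
            id=cid,
            solvent=str(raw.get("solvent", "")),
            total_energy_ha=energy,
            geometry=tuple(geometry),
            shieldings=tuple(shieldings),
            transitions=tuple(transitions),
        )
    except ValidationError as exc:
        raise EnsembleFormatError(f"conformer {cid}: {exc}") from exc


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a ``schema: 1`` ensemble document.

    Missing optional blocks (geometry, shieldings, transitions) yield empty
    fields.  Duplicate conformer ids and malformed records raise
    :class:`EnsembleFormatError` naming the offending record.
    """
    path = Path(path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise EnsembleFormatError(f"{path}: not a mapping document")
    if doc.get("schema") != SCHEMA_VERSION:
        raise EnsembleFormatError(
            f"{path}: unsupported schema version {doc.get('schema')!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    solvent = str(doc.get("solvent", ""))
    conformers = []
    for raw in doc.get("conformers", []):
        if isinstance(raw, dict):
            raw.setdefault("solvent", solvent)
        conformers.append(_parse_conformer(raw))
    references = {
        str(k): float(v) for k, v in (doc.get("references") or {}).items()
    }
    try:
        return Ensemble(
            molecule_name=str(doc.get("molecule", "")),
            conformers=tuple(conformers),
            references=references,
        )
    except ValidationError as exc:
        raise EnsembleFormatError(f"{path}: {exc}") from exc


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a ``schema: 1`` YAML document (round-trip safe)."""
    doc: dict = {
        "schema": SCHEMA_VERSION,
        "molecule": ensemble.molecule_name,
        "solvent": ensemble.solvent,
        "references": {k: float(v) for k, v in ensemble.references.items()},
        "conformers": [],
    }
    for conf in ensemble.conformers:
        raw: dict = {"id": conf.id, "total_energy_ha": float(conf.total_energy_ha)}
        if conf.geometry:
            raw["geometry"] = [
                [a.index, a.element, *[float(x) for x in a.position]]
                for a in conf.geometry
            ]
        if conf.shieldings:
            raw["shieldings"] = [
                {"atom": s.atom_index, "components": s.components.tolist()}
                for s in conf.shieldings
            ]
        if conf.transitions:
            raw["transitions"] = [
                {
                    "state": t.state_index,
                    "energy_ev": float(t.energy_ev),
                    "oscillator_strength": float(t.oscillator_strength),
                    **(
                        {"wavelength_nm": float(t.wavelength_nm)}
                        if t.wavelength_nm is not None
                        else {}
                    ),
                    **(
                        {"contributions": [[k, v] for k, v in t.contributions]}
                        if t.contributions
                        else {}
                    ),
                }
                for t in conf.transitions
            ]
        doc["conformers"].append(raw)
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# XYZ geometry
# ---------------------------------------------------------------------------

def read_xyz(path: str | Path) -> tuple[str, tuple[AtomSite, ...]]:
    """Read a standard XYZ file; returns (comment, atoms).

    Atom indices are assigned 1..n in file order.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise EnsembleFormatError(f"{path}: empty XYZ file")
    try:
        natoms = int(lines[0].strip())
    except ValueError as exc:
        raise EnsembleFormatError(f"{path}: bad atom count line") from exc
    comment = lines[1] if len(lines) > 1 else ""
    atoms = []
    for i, line in enumerate(lines[2 : 2 + natoms], start=1):
        parts = line.split()
        if len(parts) < 4:
            raise EnsembleFormatError(f"{path}: malformed XYZ line {line!r}")
        atoms.append(
            AtomSite(i, parts[0], (float(parts[1]), float(parts[2]), float(parts[3])))
        )
    if len(atoms) != natoms:
        raise EnsembleFormatError(
            f"{path}: expected {natoms} atoms, found {len(atoms)}"
        )
    return comment, tuple(atoms)


def write_xyz(atoms: Sequence[AtomSite], path: str | Path, comment: str = "") -> None:
    with Path(path).open("w") as fh:
        fh.write(f"{len(atoms)}\n{comment}\n")
        for a in sorted(atoms, key=lambda s: s.index):
            if a.position is None:
                raise ValidationError(f"atom {a.label} has no position")
            x, y, z = a.position
            fh.write(f"{a.element} {x:.8f} {y:.8f} {z:.8f}\n")


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def _parse_shift_cell(cell) -> tuple[float, tuple[float, float] | None]:
    """Parse a shift cell: a number or a printed range like ``7.67-7.69``."""
    if isinstance(cell, (int, float)) and not isinstance(cell, bool):
        return float(cell), None
    text = str(cell).strip()
    m = _RANGE_RE.match(text)
    if m:
        lo, hi = sorted((float(m.group(1)), float(m.group(2))))
        return (lo + hi) / 2.0, (lo, hi)
    try:
        return float(text), None
    except ValueError as exc:
        raise ValidationError(f"non-numeric shift cell {cell!r}") from exc


def read_peak_list(path: str | Path) -> list[ExperimentalPeak]:
    """Read a peak-list CSV (columns: nucleus, shift, [area], [label]).

    A shift written as a printed range ("7.67-7.69", en dash accepted)
    becomes a ``shift_range`` with the midpoint as ``shift``.  An empty file
    (header only or zero bytes) yields an empty list.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, dtype=str)
    if df.empty:
        return []
    cols = {c.strip().lower(): c for c in df.columns}
    if "nucleus" not in cols or "shift" not in cols:
        raise ValidationError(
            f"{path}: peak list needs 'nucleus' and 'shift' columns, "
            f"got {list(df.columns)}"
        )
    peaks = []
    for row_no, row in df.iterrows():
        try:
            shift, shift_range = _parse_shift_cell(row[cols["shift"]])
            area_cell = row[cols["area"]] if "area" in cols else None
            area = (
                float(area_cell)
                if area_cell is not None and str(area_cell) not in ("", "nan")
                else None
            )
            label_cell = row[cols["label"]] if "label" in cols else ""
            label = "" if str(label_cell) == "nan" else str(label_cell)
            peaks.append(
                ExperimentalPeak(
                    nucleus=str(row[cols["nucleus"]]).strip(),
                    shift=shift,
                    shift_range=shift_range,
                    area=area,
                    label=label,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}, row {row_no + 2}: {exc}") from exc
    return peaks


def write_peak_list(peaks: Iterable[ExperimentalPeak], path: str | Path) -> None:
    rows = []
    for p in peaks:
        shift = (
            f"{p.shift_range[0]}-{p.shift_range[1]}" if p.shift_range else p.shift
        )
        rows.append(
            {"nucleus": p.nucleus, "shift": shift, "area": p.area, "label": p.label}
        )
    pd.DataFrame(rows, columns=["nucleus", "shift", "area", "label"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

_AXIS_ALIASES = {
    "wavelength_nm": "wavelength_nm",
    "wavelength": "wavelength_nm",
    "nm": "wavelength_nm",
    "lambda_nm": "wavelength_nm",
    "energy_ev": "energy_eV",
    "energy": "energy_eV",
    "ev": "energy_eV",
}


def read_spectrum(path: str | Path, axis_kind: str | None = None) -> Spectrum:
    """Read a two-column spectrum CSV.

    The axis kind is inferred from the header (``wavelength_nm`` /
    ``energy_eV`` and common aliases) unless given explicitly.  A descending
    axis is re-sorted ascending with a logged warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: spectrum needs two columns")
    axis_col, intensity_col = df.columns[:2]
    if axis_kind is None:
        axis_kind = _AXIS_ALIASES.get(str(axis_col).strip().lower())
        if axis_kind is None:
            raise ValidationError(
                f"{path}: cannot infer axis kind from header {axis_col!r}; "
                f"pass axis_kind explicitly"
            )
    grid = df[axis_col].to_numpy(dtype=float)
    intensity = df[intensity_col].to_numpy(dtype=float)
    if np.any(np.isnan(grid)) or np.any(np.isnan(intensity)):
        raise ValidationError(f"{path}: unequal column lengths or missing values")
    order = np.argsort(grid, kind="stable")
    if not np.array_equal(order, np.arange(grid.size)):
        logger.warning("%s: axis not ascending; resorting", path)
        grid, intensity = grid[order], intensity[order]
    return Spectrum(
        axis_kind=axis_kind,
        grid=grid,
        intensity=intensity,
        metadata={"source": str(path)},
    )


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {spectrum.axis_kind: spectrum.grid, "intensity": spectrum.intensity}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures (the study's printed tables)
# ---------------------------------------------------------------------------

def _fixture(name: str) -> pd.DataFrame:
    with resources.files("confspect.data").joinpath(f"{name}.csv").open() as fh:
        return pd.read_csv(fh)


def load_energies() -> pd.DataFrame:
    """Total electronic energies (Ha) of the four conformers in both solvents,
    with the printed relative energies (kcal/mol, vs conformer 2)."""
    return _fixture("table2_energies")


def load_carbon_shifts() -> pd.DataFrame:
    """Experimental and scaled theoretical 13C shifts with atom assignments."""
    return _fixture("table3_13c")


def load_proton_shifts() -> pd.DataFrame:
    """Experimental 1H shift ranges and scaled theoretical shifts."""
    return _fixture("table4_1h")


def load_transitions() -> pd.DataFrame:
    """Selected singlet-singlet transitions (oscillator strength, nm, eV)."""
    return _fixture("table5_transitions")


def load_nbo_occupancies() -> pd.DataFrame:
    """Natural-bond-orbital occupancies for conformers 1 and 2 (fixture only)."""
    return _fixture("table1_nbo")


def tms_references() -> dict[str, float]:
    """TMS isotropic shieldings (ppm) per nucleus used as the shift zero."""
    df = _fixture("tms_references")
    return dict(zip(df["nucleus"], df["isotropic_shielding_ppm"].astype(float)))


def transitions_for(conformer: int) -> tuple[Transition, ...]:
    """The printed transitions of one conformer as :class:`Transition` objects."""
    df = load_transitions()
    rows = df[df["conformer"] == conformer]
    out = []
    for _, row in rows.iterrows():
        contributions = []
        cell = row.get("contributions")
        if isinstance(cell, str) and cell:
            for item in cell.split(";"):
                label, _, pct = item.rpartition("=")
                contributions.append((label, float(pct)))
        out.append(
            Transition(
                state_index=int(row["state"]),
                energy_ev=float(row["energy_ev"]),
                oscillator_strength=float(row["oscillator_strength"]),
                wavelength_nm=float(row["wavelength_nm"]),
                contributions=tuple(contributions),
            )
        )
    return tuple(out)


def reference_ensemble(solvent: str = "DMSO") -> Ensemble:
    """The four-conformer ensemble of the study, built from the fixtures.

    Energies come from the printed table for the requested solvent; the
    printed transition lists (computed for ethanol solutions) are attached
    when ``solvent="ethanol"``.
    """
    df = load_energies()
    rows = df[df["solvent"] == solvent]
    if rows.empty:
        raise ValidationError(
            f"no fixture energies for solvent {solvent!r}; "
            f"available: {sorted(df['solvent'].unique())}"
        )
    conformers = []
    for _, row in rows.iterrows():
        cid = int(row["conformer"])
        conformers.append(
            ConformerRecord(
                id=cid,
                solvent=solvent,
                total_energy_ha=float(row["total_energy_ha"]),
                transitions=transitions_for(cid) if solvent == "ethanol" else (),
            )
        )
    return Ensemble(
        molecule_name="N-(2-oxo-2H-chromen-3-carbonyl)cytisine",
        conformers=tuple(conformers),
        references=tms_references(),
    )


def theoretical_shift_map(nucleus: str = "13C") -> dict[tuple[str, int], float]:
    """Scaled theoretical shifts as a mapping (atom label, conformer id) -> ppm."""
    df = load_carbon_shifts() if nucleus == "13C" else load_proton_shifts()
    out: dict[tuple[str, int], float] = {}
    for _, row in df.iterrows():
        atom = str(row["atom"])
        if atom == "solvent":
            continue
        for cid in (1, 2, 3, 4):
            value = row[f"conf{cid}"]
            if pd.notna(value):
                out[(atom, cid)] = float(value)
    return out


def experimental_peaks(nucleus: str = "13C") -> list[ExperimentalPeak]:
    """The experimental peak list of the printed table for one nucleus."""
    peaks = []
    if nucleus == "13C":
        for _, row in load_carbon_shifts().iterrows():
            peaks.append(
                ExperimentalPeak(
                    nucleus="13C",
                    shift=float(row["exp_shift"]),
                    label=str(row["atom"]),
                )
            )
    elif nucleus == "1H":
        for _, row in load_proton_shifts().iterrows():
            lo, hi = float(row["exp_low"]), float(row["exp_high"])
            peaks.append(
                ExperimentalPeak(
                    nucleus="1H",
                    shift=(lo + hi) / 2.0,
                    shift_range=(lo, hi) if lo != hi else None,
                    label=str(row["atom"]),
                )
            )
    else:
        raise ValidationError(f"unknown nucleus {nucleus!r}")
    return peaks
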