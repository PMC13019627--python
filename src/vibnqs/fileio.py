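"""Force-field files, result files and parameter snapshots.

The force-field carrier is a small JSON schema (human-editable, so quartic
or sextic force fields from the literature can be transcribed into it):

```json
{
  "L": 2,
  "frequencies_cm1": [1600.0, 2200.0],
  "force_constants": [
    {"order": 3, "indices": [1, 1, 2], "value_cm1": -30.0, "reduced": true}
  ],
  "coriolis": {"B_cm1": [1.0, 0.8, 0.6], "xi": [[[0.0, ...]], ...]}
}
```

Indices are 1-based and sorted (spectroscopic convention); entries with
``"reduced": false`` are divided by the square root of the frequency
product on load.  Unknown keys are rejected.  Network parameter snapshots
go to HDF5; iteration logs are TSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .ansatz import MBFAnsatz, ModalMatrix
from .hamiltonian import Coriolis, ForceField, reduce_constants

__all__ = ["load_force_field", "save_force_field", "save_params", "load_params",
           "write_results", "config_hash"]

_TOP_KEYS = {"L", "frequencies_cm1", "force_constants", "coriolis", "comment"}
_FC_KEYS = {"order", "indices", "value_cm1", "reduced"}
_CORIOLIS_KEYS = {"B_cm1", "xi"}


class SchemaError(ValueError):
    """Raised for malformed force-field files."""


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"unknown keys {sorted(unknown)} in {where}")


def load_force_field(path) -> ForceField:
    """Read and validate a force field from the JSON schema."""
    with open(path) as fh:
        doc = json.load(fh)
    _check_keys(doc, _TOP_KEYS, str(path))
    try:
        L = int(doc["L"])
        w = np.asarray(doc["frequencies_cm1"], dtype=float)
    except KeyError as exc:
        raise SchemaError(f"missing required key {exc} in {path}") from None
    if w.shape != (L,):
        raise SchemaError(f"frequencies_cm1 must have length L={L}")

    phi: dict[int, dict[tuple, float]] = {}
    raw: dict[int, dict[tuple, float]] = {}
    for entry in doc.get("force_constants", []):
        _check_keys(entry, _FC_KEYS, "force_constants entry")
        order = int(entry["order"])
        idx = tuple(int(i) - 1 for i in entry["indices"])
        if any(i < 0 or i >= L for i in idx):
            raise SchemaError(f"1-based indices {entry['indices']} out of range for L={L}")
        if len(idx) != order:
            raise SchemaError(f"indices {entry['indices']} do not match order {order}")
        key = tuple(sorted(idx))
        target = phi if entry.get("reduced", True) else raw
        target.setdefault(order, {})
        if key in target[order]:
            raise SchemaError(f"duplicate force-constant entry {entry['indices']}")
        target[order][key] = float(entry["value_cm1"])
    for order, table in raw.items():
        reduced = reduce_constants(table, w)
        dup = set(reduced) & set(phi.get(order, {}))
        if dup:
            raise SchemaError(f"index tuples {sorted(dup)} given both reduced and raw")
        phi.setdefault(order, {}).update(reduced)

    coriolis = None
    if doc.get("coriolis") is not None:
        cdoc = doc["coriolis"]
        _check_keys(cdoc, _CORIOLIS_KEYS, "coriolis block")
        coriolis = Coriolis(b=np.asarray(cdoc["B_cm1"], dtype=float),
                            xi=np.asarray(cdoc["xi"], dtype=float))
    return ForceField(w=w, phi=phi, coriolis=coriolis)


def save_force_field(ff: ForceField, path, comment: str | None = None) -> None:
    """Write a force field in the JSON schema (reduced constants, 1-based)."""
    fcs = []
    for order in sorted(ff.phi):
        for idx in sorted(ff.phi[order]):
            fcs.append({"order": order,
                        "indices": [i + 1 for i in idx],
                        "value_cm1": ff.phi[order][idx],
                        "reduced": True})
    doc = {"L": ff.L, "frequencies_cm1": ff.w.tolist(), "force_constants": fcs}
    if ff.coriolis is not None:
        doc["coriolis"] = {"B_cm1": ff.coriolis.b.tolist(),
                           "xi": ff.coriolis.xi.tolist()}
    if comment:
        doc["comment"] = comment
    Path(path).write_text(json.dumps(doc, indent=1))


def save_params(psi: MBFAnsatz, path, seed: int | None = None) -> None:
    """Snapshot MBF parameters (shapes, alpha and seed recorded) to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.attrs["alpha"] = psi.alpha
        fh.attrs["train_phi0"] = psi.train_phi0
        fh.attrs["train_weights"] = psi.train_weights
        if seed is not None:
            fh.attrs["seed"] = int(seed)
        for name in ("w0", "b0", "w1", "b1"):
            fh.create_dataset(name, data=getattr(psi, name))
        fh.create_dataset("phi0", data=psi.phi0.phi0)


def load_params(path) -> MBFAnsatz:
    with h5py.File(path, "r") as fh:
        return MBFAnsatz(ModalMatrix(fh["phi0"][...]),
                         fh["w0"][...], fh["b0"][...], fh["w1"][...], fh["b1"][...],
                         alpha=float(fh.attrs["alpha"]),
                         train_phi0=bool(fh.attrs["train_phi0"]),
                         train_weights=bool(fh.attrs["train_weights"]))


def config_hash(cfg_doc: dict) -> str:
    """Stable short hash of a resolved configuration document."""
    blob = json.dumps(cfg_doc, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(records, zpe: float, cfg_doc: dict, path) -> None:
    """One JSON record per level: energy, transition, warnings, config hash."""
    out = {
        "config": cfg_doc,
        "config_hash": config_hash(cfg_doc),
        "zpe_cm1": zpe,
        "levels": [
            {"level": r.level,
             "energy_cm1": r.energy,
             "transition_cm1": (r.energy - zpe) if r.level > 0 else 0.0,
             "support_size": int(r.support.shape[0]),
             "warnings": list(r.warnings)}
            for r in records
        ],
    }
    Path(path).write_text(json.dumps(out, indent=1))
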