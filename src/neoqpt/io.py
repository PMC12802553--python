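"""Text serialization for coupled electron-proton Hamiltonians.

Two dialects are supported:

``neo-json``
    One JSON document with keys ``version``, ``space``, ``core_energy``,
    ``h1e``, ``h2e``, ``v1p``, ``gep``; tensors as dense row-major nested
    arrays in Hartree.

``neo-fcidump``
    A standard FCIDUMP electronic block (chemist-notation ``(ij|kl)``
    records, 1-based indices, 8-fold symmetry-reduced) followed by
    namelist-tagged extension sections ``&NEO_SPACE``, ``&NEO_V1P`` and
    ``&NEO_GEP`` holding the protonic and coupling tensors as
    index-value lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .hamiltonian import (
    DEFAULT_SYMMETRY_TOL,
    NEOHamiltonian,
    OrbitalSpace,
    ValidationError,
)

DIALECTS = ("neo-json", "neo-fcidump")


class ParseError(ValueError):
    """Malformed serialized Hamiltonian."""


# ---------------------------------------------------------------- neo-json

def _space_to_dict(space: OrbitalSpace) -> dict:
    return {
        "n_electronic_spatial": space.n_electronic_spatial,
        "n_protonic": space.n_protonic,
        "n_electrons": space.n_electrons,
        "n_protons": space.n_protons,
        "electronic_labels": list(space.electronic_labels),
        "protonic_labels": list(space.protonic_labels),
    }


def _space_from_dict(d: dict) -> OrbitalSpace:
    try:
        return OrbitalSpace(
            n_electronic_spatial=int(d["n_electronic_spatial"]),
            n_protonic=int(d["n_protonic"]),
            n_electrons=int(d["n_electrons"]),
            n_protons=int(d.get("n_protons", 1)),
            electronic_labels=tuple(d.get("electronic_labels", ())),
            protonic_labels=tuple(d.get("protonic_labels", ())),
        )
    except KeyError as exc:
        raise ParseError(f"space block missing key {exc.args[0]!r}") from exc


def _write_json(h: NEOHamiltonian, path: Path) -> None:
    doc = {
        "format": "neo-json",
        "version": 1,
        "units": "hartree",
        "space": _space_to_dict(h.space),
        "core_energy": h.core_energy,
        "h1e": h.h1e.tolist(),
        "h2e": h.h2e.tolist(),
        "v1p": h.v1p.tolist(),
        "gep": h.gep.tolist(),
    }
    path.write_text(json.dumps(doc, indent=1))


def _read_json(path: Path) -> NEOHamiltonian:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
    for key in ("space", "core_energy", "h1e", "h2e", "v1p", "gep"):
        if key not in doc:
            raise ParseError(f"{path}: missing key {key!r}")
    space = _space_from_dict(doc["space"])
    try:
        return NEOHamiltonian(
            space,
            float(doc["core_energy"]),
            np.array(doc["h1e"], dtype=float),
            np.array(doc["h2e"], dtype=float),
            np.array(doc["v1p"], dtype=float),
            np.array(doc["gep"], dtype=float),
        )
    except (ValidationError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


# -------------------------------------------------------------- neo-fcidump

def _fcidump_canonical(i: int, j: int, k: int, l: int):
    """Canonical representative of a chemist (ij|kl) under 8-fold symmetry."""
    ij = (i, j) if i >= j else (j, i)
    kl = (k, l) if k >= l else (l, k)
    return ij + kl if ij >= kl else kl + ij


def _write_fcidump(h: NEOHamiltonian, path: Path) -> None:
    sp = h.space
    n = sp.n_electronic_spatial
    lines = [
        f"&FCI NORB={n},NELEC={sp.n_electrons},MS2=0,",
        " ORBSYM=" + "1," * n,
        " ISYM=1,",
        "&END",
    ]
    seen = set()
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    # chemist (pr|qs) = physicist <pq|rs>
                    key = _fcidump_canonical(p + 1, r + 1, q + 1, s + 1)
                    if key in seen:
                        continue
                    seen.add(key)
                    val = h.h2e[p, q, r, s]
                    if val != 0.0:
                        lines.append(
                            f"{val:24.16e} {key[0]:4d} {key[1]:4d} {key[2]:4d} {key[3]:4d}"
                        )
    for p in range(n):
        for q in range(p + 1):
            val = h.h1e[p, q]
            if val != 0.0:
                lines.append(f"{val:24.16e} {p + 1:4d} {q + 1:4d} {0:4d} {0:4d}")
    lines.append(f"{h.core_energy:24.16e} {0:4d} {0:4d} {0:4d} {0:4d}")

    lines.append(f"&NEO_SPACE NPORB={sp.n_protonic},NPROT={sp.n_protons} &END")
    lines.append("&NEO_V1P")
    for P in range(sp.n_protonic):
        for Q in range(P + 1):
            val = h.v1p[P, Q]
            if val != 0.0:
                lines.append(f"{val:24.16e} {P + 1:4d} {Q + 1:4d}")
    lines.append("&END")
    lines.append("&NEO_GEP")
    for P in range(sp.n_protonic):
        for Q in range(sp.n_protonic):
            for p in range(n):
                for q in range(n):
                    val = h.gep[P, Q, p, q]
                    if val != 0.0:
                        lines.append(
                            f"{val:24.16e} {P + 1:4d} {Q + 1:4d} {p + 1:4d} {q + 1:4d}"
                        )
    lines.append("&END")
    path.write_text("\n".join(lines) + "\n")


def _read_fcidump(path: Path) -> NEOHamiltonian:
    text = path.read_text().splitlines()
    norb = nelec = nporb = None
    nprot = 1
    section = "header"
    h1e = h2e = v1p = gep = None
    core = 0.0
    for lineno, raw in enumerate(text, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("&FCI"):
            section = "fci-header"
        if section in ("header", "fci-header"):
            for token in line.replace("&FCI", "").replace(",", " ").split():
                if token.startswith("NORB="):
                    norb = int(token[5:])
                elif token.startswith("NELEC="):
                    nelec = int(token[6:])
            if upper.startswith("&END") or upper.endswith("&END"):
                if norb is None or nelec is None:
                    raise ParseError(f"{path}:{lineno}: missing NORB/NELEC in header")
                h1e = np.zeros((norb, norb))
                h2e = np.zeros((norb,) * 4)
                section = "integrals"
            continue
        if upper.startswith("&NEO_SPACE"):
            for token in line.replace("&NEO_SPACE", "").replace("&END", "").replace(
                ",", " "
            ).split():
                if token.startswith("NPORB="):
                    nporb = int(token[6:])
                elif token.startswith("NPROT="):
                    nprot = int(token[6:])
            if nporb is None:
                raise ParseError(f"{path}:{lineno}: &NEO_SPACE missing NPORB")
            v1p = np.zeros((nporb, nporb))
            gep = np.zeros((nporb, nporb, norb, norb))
            continue
        if upper.startswith("&NEO_V1P"):
            section = "v1p"
            continue
        if upper.startswith("&NEO_GEP"):
            section = "gep"
            continue
        if upper.startswith("&END"):
            section = "done"
            continue

        fields = line.split()
        try:
            val = float(fields[0])
            idx = [int(f) for f in fields[1:]]
        except (ValueError, IndexError):
            raise ParseError(f"{path}:{lineno}: malformed record {line!r}")

        if section == "integrals":
            if len(idx) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 indices")
            i, j, k, l = idx
            if i == j == k == l == 0:
                core = val
            elif k == l == 0:
                if not (1 <= i <= norb and 1 <= j <= norb):
                    raise ParseError(f"{path}:{lineno}: orbital index out of range")
                h1e[i - 1, j - 1] = val
                h1e[j - 1, i - 1] = val
            else:
                if not all(1 <= t <= norb for t in idx):
                    raise ParseError(f"{path}:{lineno}: orbital index out of range")
                for a, b in ((i, j), (j, i)):
                    for c, d in ((k, l), (l, k)):
                        # chemist (ab|cd) = physicist <ac|bd>
                        h2e[a - 1, c - 1, b - 1, d - 1] = val
                        h2e[c - 1, a - 1, d - 1, b - 1] = val
        elif section == "v1p":
            if v1p is None:
                raise ParseError(f"{path}:{lineno}: &NEO_V1P before &NEO_SPACE")
            if len(idx) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 indices")
            P, Q = idx
            if not (1 <= P <= nporb and 1 <= Q <= nporb):
                raise ParseError(f"{path}:{lineno}: protonic index out of range")
            v1p[P - 1, Q - 1] = val
            v1p[Q - 1, P - 1] = val
        elif section == "gep":
            if gep is None:
                raise ParseError(f"{path}:{lineno}: &NEO_GEP before &NEO_SPACE")
            if len(idx) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 indices")
            P, Q, p, q = idx
            if not (1 <= P <= nporb and 1 <= Q <= nporb):
                raise ParseError(f"{path}:{lineno}: protonic index out of range")
            if not (1 <= p <= norb and 1 <= q <= norb):
                raise ParseError(f"{path}:{lineno}: electronic index out of range")
            gep[P - 1, Q - 1, p - 1, q - 1] = val
        else:
            raise ParseError(f"{path}:{lineno}: unexpected record outside any section")

    if h1e is None:
        raise ParseError(f"{path}: no FCIDUMP header found")
    if v1p is None or gep is None:
        raise ParseError(f"{path}: missing &NEO_SPACE extension block")
    space = OrbitalSpace(
        n_electronic_spatial=norb, n_protonic=nporb, n_electrons=nelec, n_protons=nprot
    )
    return NEOHamiltonian(space, core, h1e, h2e, v1p, gep)


# ---------------------------------------------------------------- frontend

def write_hamiltonian(
    h: NEOHamiltonian,
    path: Union[str, Path],
    dialect: str = "neo-json",
    tol: float = DEFAULT_SYMMETRY_TOL,
) -> Path:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    h.validate(tol)
    path = Path(path)
    if dialect == "neo-json":
        _write_json(h, path)
    else:
        _write_fcidump(h, path)
    return path


def read_hamiltonian(
    path: Union[str, Path],
    dialect: str = "neo-json",
    tol: float = DEFAULT_SYMMETRY_TOL,
) -> NEOHamiltonian:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    path = Path(path)
    h = _read_json(path) if dialect == "neo-json" else _read_fcidump(path)
    h.validate(tol)
    return h


def write_matrix(m: np.ndarray, path: Union[str, Path], name: str = "matrix") -> Path:
    path = Path(path)
    path.write_text(json.dumps({"name": name, "matrix": np.asarray(m).tolist()}))
    return path


def read_matrix(path: Union[str, Path]) -> np.ndarray:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
    if "matrix" not in doc:
        raise ParseError(f"{path}: missing key 'matrix'")
    m = np.array(doc["matrix"], dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParseError(f"{path}: matrix is not square")
    return m
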