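"""Second-quantized fermionic operators, Jordan-Wigner mapping and
fixed-particle-number sector machinery.

Modes are indexed 0..n_modes-1.  A determinant is the ordered product
``a†_{i1} ... a†_{ik} |vac>`` with i1 < ... < ik; under Jordan-Wigner
(with qubit q on bit q) this state maps to the computational basis
state whose set bits are the occupied modes, with coefficient +1.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .pauli import PauliSum

# one term: (coefficient, ((mode, is_creation), ...)) applied right-to-left
FermionTerm = Tuple[complex, Tuple[Tuple[int, bool], ...]]


def jw_lowering(mode: int, n_qubits: int) -> PauliSum:
    """JW image of the annihilation operator a_mode."""
    zchain = (1 << mode) - 1
    x = 1 << mode
    # (X + iY)/2 with the Z chain folded into the masks; the (x, z|x) key
    # already carries the i^{|x&z|} normal-form factor that makes it Y
    return PauliSum(n_qubits, {(x, zchain): 0.5, (x, zchain | x): 0.5j})


def _jw_op(mode: int, creation: bool, n_qubits: int) -> PauliSum:
    low = jw_lowering(mode, n_qubits)
    return low.dagger() if creation else low


def jordan_wigner(terms: Sequence[FermionTerm], n_qubits: int,
                  constant: float = 0.0) -> PauliSum:
    """Map a sum of fermionic operator products to a PauliSum."""
    out = PauliSum.identity(n_qubits, constant) if constant else PauliSum.zero(n_qubits)
    for coeff, ops in terms:
        if not ops:
            out = out + PauliSum.identity(n_qubits, coeff)
            continue
        prod = _jw_op(ops[0][0], ops[0][1], n_qubits)
        for mode, creation in ops[1:]:
            prod = prod * _jw_op(mode, creation, n_qubits)
        out = out + prod * coeff
    return out.prune()


def apply_term_to_det(ops: Tuple[Tuple[int, bool], ...], det: int
                      ) -> Tuple[int, int] | None:
    """Apply an operator product (right-to-left) to a determinant bitmask.

    Returns (sign, new_det) or None when annihilated.
    """
    sign = 1
    for mode, creation in reversed(ops):
        bit = 1 << mode
        occupied = det & bit
        if creation:
            if occupied:
                return None
            if (det & (bit - 1)).bit_count() & 1:
                sign = -sign
            det |= bit
        else:
            if not occupied:
                return None
            if (det & (bit - 1)).bit_count() & 1:
                sign = -sign
            det &= ~bit
    return sign, det


def sector_determinants(n_elec_spin: int, n_electrons: int,
                        n_protonic: int, n_protons: int) -> List[int]:
    """Bitmasks of all determinants with fixed electron and proton numbers.

    Electronic modes occupy bits [0, n_elec_spin); protonic modes the next
    n_protonic bits.  Ordering is lexicographic with the electronic
    configuration fastest.
    """
    e_masks = [
        sum(1 << i for i in combo)
        for combo in combinations(range(n_elec_spin), n_electrons)
    ]
    p_masks = [
        sum(1 << (n_elec_spin + i) for i in combo)
        for combo in combinations(range(n_protonic), n_protons)
    ]
    return [p | e for p in p_masks for e in e_masks]


def build_sector_matrix(terms: Sequence[FermionTerm], dets: Sequence[int],
                        constant: float = 0.0) -> sp.csr_matrix:
    """Matrix of a fermionic operator in the given determinant basis."""
    index = {d: i for i, d in enumerate(dets)}
    rows: List[int] = []
    cols: List[int] = []
    vals: List[complex] = []
    for j, det in enumerate(dets):
        for coeff, ops in terms:
            hit = apply_term_to_det(ops, det)
            if hit is None:
                continue
            sign, new_det = hit
            i = index.get(new_det)
            if i is None:
                continue
            rows.append(i)
            cols.append(j)
            vals.append(sign * coeff)
    n = len(dets)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if constant:
        mat = mat + sp.identity(n, format="csr") * constant
    return mat


def det_to_statevector(det: int, n_qubits: int) -> np.ndarray:
    psi = np.zeros(1 << n_qubits, dtype=complex)
    psi[det] = 1.0
    return psi


def sector_vector_to_statevector(vec: np.ndarray, dets: Sequence[int],
                                 n_qubits: int) -> np.ndarray:
    """Embed a sector-basis vector into the full 2**n qubit space."""
    psi = np.zeros(1 << n_qubits, dtype=complex)
    for amp, det in zip(vec, dets):
        psi[det] = amp
    return psi


def number_operator_terms(modes: Sequence[int]) -> List[FermionTerm]:
    return [(1.0, ((m, True), (m, False))) for m in modes]


def restrict_dense(mat: np.ndarray | sp.spmatrix, dets: Sequence[int]) -> np.ndarray:
    """Restrict a full 2**n operator matrix to the determinant sector."""
    idx = np.asarray(dets, dtype=np.int64)
    if sp.issparse(mat):
        return np.asarray(mat[np.ix_(idx, idx)].todense())
    return mat[np.ix_(idx, idx)]
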