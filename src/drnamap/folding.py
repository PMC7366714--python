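"""Minimum-free-energy folding of short RNAs over nested secondary structures.

The bundled reference backend is a dynamic program over nested (pseudoknot-
free) structures with a simple additive energy model:

* pair energies: G:C -3, A:U -2, G:U -1 kcal/mol
* minimum hairpin loop of 3 unpaired nt
* a +4 kcal/mol penalty per hairpin loop (pairs enclosing no other pair)

This deliberately transparent model serves the pipeline's folding-energy
filter; an external thermodynamic engine (ViennaRNA's ``RNAfold`` binary)
can be selected with ``backend="vienna"`` where installed.
"""

from __future__ import annotations

import shutil
import subprocess

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

HAIRPIN_PENALTY = 4.0
MIN_LOOP = 3
_INF = 1e30

# base encoding: A=0 C=1 G=2 U=3, anything else 4 (unpairable)
_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair energy table indexed [b1][b2]; 0 = cannot pair
_PAIR_E = np.zeros((5, 5), dtype=np.float64)
_PAIR_E[2, 1] = _PAIR_E[1, 2] = -3.0   # G:C
_PAIR_E[0, 3] = _PAIR_E[3, 0] = -2.0   # A:U
_PAIR_E[2, 3] = _PAIR_E[3, 2] = -1.0   # G:U


def _validate_rna(sequence: str) -> str:
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq


def encode(sequence: str) -> np.ndarray:
    seq = _validate_rna(sequence)
    return np.array([_ENCODE.get(c, 4) for c in seq], dtype=np.int8)


@njit(cache=True)
def _mfe_dp(enc, pair_e):  # pragma: no cover - exercised via fold_energy
    n = enc.shape[0]
    if n == 0:
        return 0.0
    W = np.zeros((n + 1, n + 1))          # best energy on [i, j); always <= 0
    Wp = np.full((n + 1, n + 1), _INF)    # best energy with >= 1 pair
    V = np.full((n, n), _INF)             # best energy with (i, j-1)... see below
    # V[i][j]: best energy on [i, j] inclusive with i paired to j.
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1  # inclusive end
            e = pair_e[enc[i], enc[j]]
            if e < 0.0:
                best = _INF
                inner = j - i - 1
                if inner >= MIN_LOOP:
                    best = HAIRPIN_PENALTY
                if inner >= 2 and Wp[i + 1, j] < _INF / 2:
                    # Wp over [i+1, j) inclusive-exclusive == bases i+1..j-1
                    if Wp[i + 1, j] < best:
                        best = Wp[i + 1, j]
                if best < _INF / 2:
                    V[i, j] = e + best
            # W / Wp over half-open [i, j+1)
            w = W[i + 1, j + 1]
            wp = Wp[i + 1, j + 1]
            for k in range(i + 1, j + 1):
                if V[i, k] < _INF / 2:
                    rest = W[k + 1, j + 1]
                    cand = V[i, k] + rest
                    if cand < w:
                        w = cand
                    if cand < wp:
                        wp = cand
            if w > 0.0:
                w = 0.0
            W[i, j + 1] = w
            Wp[i, j + 1] = wp
    return W[0, n]


def fold_energy_reference(sequence: str) -> float:
    """MFE (kcal/mol, <= 0) of ``sequence`` under the bundled reference model."""
    enc = encode(sequence)
    if enc.shape[0] < 2:
        return 0.0
    return float(_mfe_dp(enc, _PAIR_E))


def fold_energy_vienna(sequence: str) -> float:
    """MFE via the external ``RNAfold`` binary (nearest-neighbor model)."""
    seq = _validate_rna(sequence)
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold binary not found on PATH")
    out = subprocess.run([exe, "--noPS"], input=seq + "\n", text=True,
                         capture_output=True, check=True).stdout
    line = out.strip().splitlines()[-1]
    energy = line[line.rindex("(") + 1: line.rindex(")")]
    return float(energy)


_BACKENDS = {"reference": fold_energy_reference, "vienna": fold_energy_vienna}


def fold_energy(sequence: str, backend="reference") -> float:
    """Folding free-energy change of the MFE nested structure.

    ``backend`` may be ``"reference"`` (bundled dynamic program),
    ``"vienna"`` (external RNAfold), or any callable ``str -> float``.
    """
    if callable(backend):
        return backend(sequence)
    try:
        fn = _BACKENDS[backend]
    except KeyError:
        raise ValueError(f"unknown folding backend {backend!r}") from None
    return fn(sequence)


def normalized_energy(sequence: str, backend="reference") -> float:
    """Folding energy divided by sequence length (kcal/mol per nt)."""
    if not sequence:
        raise ValueError("empty sequence")
    return fold_energy(sequence, backend=backend) / len(sequence)
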