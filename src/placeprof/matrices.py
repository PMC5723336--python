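"""Amino-acid exchangeability matrices (LG, WAG, JTT) and score matrices.

Rate-matrix files are plain text in the conventional lower-triangle layout
(19 rows of exchangeabilities, blank line, 20 stationary frequencies) in
the standard residue order ARNDCQEGHILKMFPSTWYV.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_AVAILABLE = ("LG", "WAG", "JTT")


def available_matrices() -> tuple[str, ...]:
    return _AVAILABLE


def load_exchangeabilities(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (symmetric 20x20 exchangeability matrix, stationary freqs)."""
    key = name.upper()
    if key not in _AVAILABLE:
        raise ValueError(
            f"unknown substitution matrix {name!r}; choose from {_AVAILABLE}"
        )
    text = (
        resources.files("placeprof.data").joinpath(f"{key.lower()}.dat").read_text()
    )
    numbers = [float(x) for x in text.split()]
    if len(numbers) != 190 + 20:
        raise ValueError(f"malformed matrix file for {key}")
    R = np.zeros((20, 20))
    idx = 0
    for i in range(1, 20):
        for j in range(i):
            R[i, j] = R[j, i] = numbers[idx]
            idx += 1
    freqs = np.asarray(numbers[190:], dtype=float)
    freqs = freqs / freqs.sum()
    return R, freqs


def blosum_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """20x20 protein score matrix in AA_ORDER, from biopython's tables."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load(name)
    out = np.zeros((20, 20))
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            out[i, j] = m[a, b]
    return out


def encode_aa(seq: str) -> np.ndarray:
    """Encode an amino-acid string as indices into AA_ORDER; unknown
    residues (X, ambiguity, stop) encode as -1."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=np.int64)
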