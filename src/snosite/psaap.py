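"""Position-Specific Amino Acid Propensity (PSAAP) features.

The feature representation contrasts, position by position, how often each of
the 21 residue symbols occurs in the flanks of modified (positive) versus
unmodified (negative) cysteine windows.  From the two class-conditional
frequency matrices ``p+`` and ``p-`` (21 rows = residue codes, 2*xi columns =
flank offsets -xi..-1, +1..+xi), the propensity matrix is

    Z(i, j) = p+(i, j) - p-(i, j)          (difference functional, default)
    Z(i, j) = ln(p+_a(i, j) / p-_a(i, j))  (log-odds, add-a smoothed counts)

A window is encoded as the pseudo-amino-acid-composition style vector
``(Psi_1, ..., Psi_{2*xi})`` where ``Psi_u`` looks up the propensity of the
residue observed at the u-th non-center position: the central cysteine is
constant by construction and is omitted.

The difference functional is bounded in [-1, 1], antisymmetric under class
swap, and identically zero when the two classes have the same composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyTrainingSetError, FormatError, ParameterError, ShapeError
from .windowing import DEFAULT_ALPHABET, PeptideWindow, ResidueAlphabet

FUNCTIONALS = ("difference", "log_odds")


def offsets(xi: int) -> list[int]:
    """Flank offsets in column order: -xi..-1 then +1..+xi."""
    return list(range(-xi, 0)) + list(range(1, xi + 1))


@dataclass(frozen=True)
class FrequencyMatrix:
    """Column-wise residue occurrence frequencies over one window set.

    ``values[i, j] = (count of residue code i+1 at offset j + a) / (n + 21 a)``
    with pseudocount ``a``; at ``a = 0`` every column sums to 1 exactly.
    """

    values: np.ndarray
    xi: int
    n_windows: int
    pseudocount: float


@dataclass(frozen=True)
class PSAAPMatrix:
    """21 x 2*xi propensity matrix with its provenance."""

    values: np.ndarray
    xi: int
    functional: str
    pseudocount: float
    n_pos: int
    n_neg: int


def _codes_matrix(
    windows: Sequence[PeptideWindow], alphabet: ResidueAlphabet
) -> np.ndarray:
    """0-based residue indices of all flanks, shape (n_windows, 2*xi)."""
    index = {s: i for i, s in enumerate(alphabet.symbols)}
    return np.array([[index[ch] for ch in w.flanks] for w in windows], dtype=np.intp)


def _common_xi(windows: Sequence[PeptideWindow]) -> int:
    xis = {w.xi for w in windows}
    if len(xis) != 1:
        raise ShapeError(f"windows mix half-widths {sorted(xis)}")
    return xis.pop()


def frequency_matrix(
    windows: Sequence[PeptideWindow],
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
    pseudocount: float = 0.0,
) -> FrequencyMatrix:
    """Tally per-offset residue frequencies over a window set.

    Columns are ordered -xi..-1, +1..+xi; the constant central cysteine is
    excluded.  X (code 21) is a first-class row, so terminal padding
    contributes to the composition like any residue.
    """
    windows = list(windows)
    if not windows:
        raise EmptyTrainingSetError("cannot tally frequencies of an empty window set")
    if pseudocount < 0:
        raise ParameterError(f"pseudocount must be >= 0, got {pseudocount}")
    xi = _common_xi(windows)
    codes = _codes_matrix(windows, alphabet)
    n = len(windows)
    counts = np.zeros((len(alphabet), 2 * xi), dtype=float)
    for j in range(2 * xi):
        counts[:, j] = np.bincount(codes[:, j], minlength=len(alphabet))
    values = (counts + pseudocount) / (n + len(alphabet) * pseudocount)
    return FrequencyMatrix(values=values, xi=xi, n_windows=n, pseudocount=pseudocount)


def build_psaap(
    positives: Sequence[PeptideWindow],
    negatives: Sequence[PeptideWindow],
    functional: str = "difference",
    pseudocount: float | None = None,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
) -> PSAAPMatrix:
    """Contrast positive against negative frequencies into a propensity matrix.

    ``pseudocount`` defaults to 0 for the difference functional (frequencies
    are well defined without smoothing) and to 1 for log-odds (add-one over
    the 21-symbol alphabet, which keeps every ratio finite).
    """
    if functional not in FUNCTIONALS:
        raise ParameterError(f"functional must be one of {FUNCTIONALS}, got {functional!r}")
    if pseudocount is None:
        pseudocount = 0.0 if functional == "difference" else 1.0
    if functional == "log_odds" and pseudocount <= 0:
        raise ParameterError("log_odds functional requires pseudocount > 0")
    pos = frequency_matrix(positives, alphabet, pseudocount)
    neg = frequency_matrix(negatives, alphabet, pseudocount)
    if pos.xi != neg.xi:
        raise ShapeError(f"positive xi={pos.xi} differs from negative xi={neg.xi}")
    if functional == "difference":
        values = pos.values - neg.values
    else:
        values = np.log(pos.values / neg.values)
    return PSAAPMatrix(
        values=values,
        xi=pos.xi,
        functional=functional,
        pseudocount=pseudocount,
        n_pos=pos.n_windows,
        n_neg=neg.n_windows,
    )


def encode(
    window: PeptideWindow,
    psaap: PSAAPMatrix,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
) -> np.ndarray:
    """Feature vector ``Psi_u = Z(code of u-th flank residue, offset u)``."""
    if window.xi != psaap.xi:
        raise ShapeError(f"window xi={window.xi} does not match matrix xi={psaap.xi}")
    idx = [alphabet.index_of(ch) for ch in window.flanks]
    return psaap.values[idx, np.arange(2 * psaap.xi)]


def encode_many(
    windows: Sequence[PeptideWindow],
    psaap: PSAAPMatrix,
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET,
) -> np.ndarray:
    """Stack :func:`encode` over windows into shape (n, 2*xi)."""
    windows = list(windows)
    if not windows:
        return np.zeros((0, 2 * psaap.xi))
    if _common_xi(windows) != psaap.xi:
        raise ShapeError("window xi does not match matrix xi")
    codes = _codes_matrix(windows, alphabet)
    return psaap.values[codes, np.arange(2 * psaap.xi)]


# --- serialization: UTF-8 TSV, one header line then 21 labelled rows -------


def save_psaap(psaap: PSAAPMatrix, alphabet: ResidueAlphabet = DEFAULT_ALPHABET) -> str:
    """Render a PSAAP matrix as TSV text (lossless float round trip)."""
    header = (
        f"#psaap\txi={psaap.xi}\tfunctional={psaap.functional}"
        f"\tpseudocount={psaap.pseudocount!r}\tn_pos={psaap.n_pos}\tn_neg={psaap.n_neg}"
    )
    cols = "\t".join(str(o) for o in offsets(psaap.xi))
    lines = [header, f"residue\t{cols}"]
    for i, sym in enumerate(alphabet.symbols):
        row = "\t".join(repr(v) for v in psaap.values[i].tolist())
        lines.append(f"{sym}\t{row}")
    return "\n".join(lines) + "\n"


def load_psaap(text: str, alphabet: ResidueAlphabet = DEFAULT_ALPHABET) -> PSAAPMatrix:
    """Parse the TSV produced by :func:`save_psaap`."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("#psaap"):
        raise FormatError("not a PSAAP table: missing '#psaap' header")
    meta: dict[str, str] = {}
    for tok in lines[0].split("\t")[1:]:
        if "=" not in tok:
            raise FormatError(f"malformed header token {tok!r}")
        key, val = tok.split("=", 1)
        meta[key] = val
    try:
        xi = int(meta["xi"])
        functional = meta["functional"]
        pseudocount = float(meta["pseudocount"])
        n_pos = int(meta["n_pos"])
        n_neg = int(meta["n_neg"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"incomplete or malformed PSAAP header: {exc}") from exc
    if functional not in FUNCTIONALS:
        raise FormatError(f"unknown functional {functional!r}")
    body = lines[2:]  # skip the offset header row
    if len(body) != len(alphabet):
        raise FormatError(f"expected {len(alphabet)} residue rows, found {len(body)}")
    values = np.zeros((len(alphabet), 2 * xi))
    for i, (sym, line) in enumerate(zip(alphabet.symbols, body)):
        parts = line.split("\t")
        if parts[0] != sym:
            raise FormatError(f"row {i + 1}: expected residue {sym!r}, found {parts[0]!r}")
        if len(parts) - 1 != 2 * xi:
            raise FormatError(
                f"row {sym!r}: expected {2 * xi} columns for xi={xi}, found {len(parts) - 1}"
            )
        try:
            values[i] = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise FormatError(f"row {sym!r}: non-numeric entry ({exc})") from exc
    return PSAAPMatrix(
        values=values,
        xi=xi,
        functional=functional,
        pseudocount=pseudocount,
        n_pos=n_pos,
        n_neg=n_neg,
    )
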