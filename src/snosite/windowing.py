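"""Cysteine-centered peptide windows and the 21-symbol residue alphabet.

An S-nitrosylation site is a cysteine; its sequence context is captured by a
``(2*xi + 1)``-mer window centered on that cysteine.  Flanking positions that
run past a protein terminus are filled with the dummy symbol ``X``, so every
window has the same length regardless of where the site sits in the protein.

The residue alphabet has 21 symbols: the 20 native amino acids, numbered
1..20 in the alphabetical order of their one-letter codes, plus ``X`` as
symbol 21.  All matrix code downstream indexes residues in this order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Literal

from .errors import (
    BoundsError,
    InvalidSequenceError,
    NotACysteineError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: One-letter codes of the 20 native amino acids, alphabetical.
NATIVE_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Dummy symbol for positions beyond a protein terminus (code 21).
PAD_SYMBOL = "X"

#: Default window half-width: 10 residues each side of the cysteine (21-mers).
DEFAULT_XI = 10

Label = Literal["positive", "negative", "unknown"]


@dataclass(frozen=True)
class ResidueAlphabet:
    """Ordered 21-symbol alphabet with a bijection onto codes 1..21."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) != 21 or len(set(self.symbols)) != 21:
            raise ValueError("alphabet must hold exactly 21 distinct symbols")
        if self.symbols[-1] != PAD_SYMBOL:
            raise ValueError(f"pad symbol {PAD_SYMBOL!r} must carry code 21")

    @cached_property
    def code_of(self) -> dict[str, int]:
        """Symbol -> 1-based numeric code (A=1 ... Y=20, X=21)."""
        return {s: i + 1 for i, s in enumerate(self.symbols)}

    def index_of(self, symbol: str) -> int:
        """Symbol -> 0-based row index used by matrices."""
        return self.code_of[symbol] - 1

    def __len__(self) -> int:
        return len(self.symbols)


#: The canonical alphabet: A..Y alphabetical, then X.
DEFAULT_ALPHABET = ResidueAlphabet(tuple(NATIVE_AMINO_ACIDS) + (PAD_SYMBOL,))


@dataclass(frozen=True)
class ProteinRecord:
    """A sanitized protein sequence with its accession/description."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidSequenceError(f"protein {self.id!r} has empty sequence")
        bad = set(self.sequence) - set(DEFAULT_ALPHABET.symbols)
        if bad:
            raise InvalidSequenceError(
                f"protein {self.id!r} contains unsanitized symbols {sorted(bad)}; "
                "run sanitize_sequence first"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """One cysteine-centered ``(2*xi + 1)``-mer with provenance.

    ``site`` is the 1-based position of the central cysteine in the parent
    protein.  ``center_warning`` marks windows extracted in permissive mode
    around a non-cysteine residue.
    """

    protein_id: str
    site: int
    residues: str
    xi: int
    label: Label = "unknown"
    center_warning: bool = False

    def __post_init__(self) -> None:
        if self.xi < 1:
            raise ParameterError(f"xi must be >= 1, got {self.xi}")
        if len(self.residues) != 2 * self.xi + 1:
            raise ParameterError(
                f"window must be {2 * self.xi + 1}-mer for xi={self.xi}, "
                f"got length {len(self.residues)}"
            )
        if self.residues[self.xi] != "C" and not self.center_warning:
            raise NotACysteineError(
                f"window center is {self.residues[self.xi]!r}, not 'C' "
                f"({self.protein_id} site {self.site})"
            )

    @property
    def flanks(self) -> str:
        """The 2*xi non-center residues, N-terminal to C-terminal."""
        return self.residues[: self.xi] + self.residues[self.xi + 1 :]


def sanitize_sequence(raw: str) -> str:
    """Normalize a raw sequence onto the 21-symbol alphabet.

    Whitespace is removed, letters are uppercased, and any character outside
    the 20 native codes (B, J, O, U, Z, ``*``, ``-``, digits, ...) is replaced
    by ``X``.  The number of replacements is reported through logging.
    """
    seq = "".join(raw.split()).upper()
    if not seq:
        raise InvalidSequenceError("sequence is empty after stripping whitespace")
    allowed = set(NATIVE_AMINO_ACIDS)
    out = []
    replaced = 0
    for ch in seq:
        if ch in allowed:
            out.append(ch)
        else:
            out.append(PAD_SYMBOL)
            if ch != PAD_SYMBOL:
                replaced += 1
    if replaced:
        logger.warning("sanitize_sequence: replaced %d non-standard residue(s) with X", replaced)
    return "".join(out)


def _window_residues(sequence: str, site: int, xi: int) -> str:
    """Slice the closed interval [site-xi, site+xi] (1-based), X-padded."""
    n = len(sequence)
    left_pad = max(0, xi - site + 1)
    right_pad = max(0, site + xi - n)
    lo = max(0, site - 1 - xi)
    hi = min(n, site + xi)
    return PAD_SYMBOL * left_pad + sequence[lo:hi] + PAD_SYMBOL * right_pad


def window_at(
    protein: ProteinRecord,
    site: int,
    xi: int = DEFAULT_XI,
    strict: bool = True,
    label: Label = "unknown",
) -> PeptideWindow:
    """Window centered at a 1-based ``site`` of a sanitized protein.

    In strict mode (default) a non-cysteine center raises
    :class:`~snosite.errors.NotACysteineError`; permissive mode returns the
    window flagged with ``center_warning``.
    """
    if xi < 1:
        raise ParameterError(f"xi must be >= 1, got {xi}")
    if not 1 <= site <= len(protein.sequence):
        raise BoundsError(
            f"site {site} out of range 1..{len(protein.sequence)} for {protein.id!r}"
        )
    residues = _window_residues(protein.sequence, site, xi)
    center_warning = False
    if residues[xi] != "C":
        if strict:
            raise NotACysteineError(
                f"residue at site {site} of {protein.id!r} is {residues[xi]!r}, not 'C'"
            )
        center_warning = True
        logger.warning(
            "window_at: permissive window at non-cysteine site %d of %r", site, protein.id
        )
    return PeptideWindow(
        protein_id=protein.id,
        site=site,
        residues=residues,
        xi=xi,
        label=label,
        center_warning=center_warning,
    )


def extract_windows(protein: ProteinRecord, xi: int = DEFAULT_XI) -> list[PeptideWindow]:
    """One window per cysteine, in ascending site order.

    Proteins without cysteine yield the empty list.
    """
    if xi < 1:
        raise ParameterError(f"xi must be >= 1, got {xi}")
    return [
        window_at(protein, site=i + 1, xi=xi)
        for i, ch in enumerate(protein.sequence)
        if ch == "C"
    ]
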