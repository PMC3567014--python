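"""Benchmark-shaped synthetic data with planted positional propensities.

The generator emulates the statistical structure a position-specific
propensity matrix is built to detect: negative windows draw every flank
position i.i.d. from a background residue composition, while positive
windows use per-position distributions shifted by planted enrichments.  An
enrichment ``(offset, residue, e)`` moves probability mass ``e`` onto that
residue at that offset (the remaining residues are scaled down to
renormalize), so the expected difference-functional propensity at the
planted cell is exactly ``e``.

Terminal truncation is emulated by overwriting, with probability
``terminal_pad_prob``, a uniformly drawn number of residues at one window
end with the dummy symbol ``X`` — the shape real benchmarks acquire when a
site sits within ``xi`` residues of a protein terminus.

Window provenance (protein accession, 1-based site) is nominal: windows are
distributed round-robin over ``n_proteins`` synthetic accessions with
regularly spaced sites, which satisfies the benchmark-table invariants
(center C, unique (protein, site)) but is not meant to be arithmetically
consistent with the X-runs of truncated windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SyntheticSpecError
from .windowing import (
    DEFAULT_ALPHABET,
    DEFAULT_XI,
    NATIVE_AMINO_ACIDS,
    PeptideWindow,
    ProteinRecord,
)

#: Approximate Swiss-Prot residue composition (alphabetical order), an
#: alternative to the uniform background for more lifelike sequences.
SWISSPROT_BACKGROUND = np.array(
    [
        0.0825, 0.0137, 0.0545, 0.0675, 0.0386, 0.0707, 0.0227, 0.0596,
        0.0584, 0.0966, 0.0242, 0.0406, 0.0470, 0.0393, 0.0553, 0.0656,
        0.0534, 0.0687, 0.0108, 0.0292,
    ]
)
SWISSPROT_BACKGROUND = SWISSPROT_BACKGROUND / SWISSPROT_BACKGROUND.sum()

#: Moderate acid/base-flavoured motif: realistic PTM-motif effect sizes.
DEFAULT_ENRICHMENTS: tuple[tuple[int, str, float], ...] = (
    (-2, "K", 0.15),
    (-1, "E", 0.15),
    (1, "D", 0.15),
    (2, "R", 0.15),
    (-5, "L", 0.10),
    (5, "G", 0.10),
)

#: Strong, clearly separable motif (five offsets, effect 0.6 each).
STRONG_ENRICHMENTS: tuple[tuple[int, str, float], ...] = (
    (-4, "K", 0.6),
    (-2, "E", 0.6),
    (-1, "D", 0.6),
    (1, "E", 0.6),
    (3, "R", 0.6),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Conditions under which a synthetic benchmark is drawn.

    Defaults mirror the published benchmark's dimensions: 731 positive and
    810 negative 21-mers spread over 438 protein accessions, with roughly one
    window in ten truncated at a terminus.
    """

    xi: int = DEFAULT_XI
    n_pos: int = 731
    n_neg: int = 810
    background: np.ndarray | None = None  # length 20 over natives; None = uniform
    enrichments: tuple[tuple[int, str, float], ...] = DEFAULT_ENRICHMENTS
    terminal_pad_prob: float = 0.1
    n_proteins: int = 438
    seed: int = 42

    def background_vector(self) -> np.ndarray:
        if self.background is None:
            return np.full(20, 1.0 / 20)
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise SyntheticSpecError("background must be a length-20 probability vector")
        return bg / bg.sum()


def _column_distributions(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-offset residue distributions, shapes (2*xi, 21): positive, negative.

    Column order matches the propensity matrix: offsets -xi..-1, +1..+xi.
    The X symbol has zero base mass; X arises only from terminal truncation.
    """
    bg20 = spec.background_vector()
    bg = np.concatenate([bg20, [0.0]])  # X gets code 21, zero base mass
    cols = list(range(-spec.xi, 0)) + list(range(1, spec.xi + 1))
    neg = np.tile(bg, (2 * spec.xi, 1))
    pos = neg.copy()
    by_offset: dict[int, list[tuple[str, float]]] = {}
    for off, res, e in spec.enrichments:
        if off == 0 or abs(off) > spec.xi:
            raise SyntheticSpecError(f"enrichment offset {off} outside flanks for xi={spec.xi}")
        if res not in NATIVE_AMINO_ACIDS:
            raise SyntheticSpecError(f"enrichment residue {res!r} is not a native amino acid")
        if not -1.0 <= e <= 1.0:
            raise SyntheticSpecError(f"enrichment effect {e} outside [-1, 1]")
        by_offset.setdefault(off, []).append((res, e))
    for off, items in by_offset.items():
        j = cols.index(off)
        col = pos[j].copy()
        enriched_idx = [DEFAULT_ALPHABET.index_of(r) for r, _ in items]
        targets = {}
        for (res, e), idx in zip(items, enriched_idx):
            targets[idx] = col[idx] + e
        if any(t < 0 or t > 1 for t in targets.values()) or sum(targets.values()) > 1:
            raise SyntheticSpecError(
                f"enrichments at offset {off} leave no valid probability mass"
            )
        rest_mass_old = 1.0 - sum(col[i] for i in targets)
        rest_mass_new = 1.0 - sum(targets.values())
        if rest_mass_old <= 0 and rest_mass_new > 0:
            raise SyntheticSpecError(f"offset {off}: no residual mass to rescale")
        scale = rest_mass_new / rest_mass_old if rest_mass_old > 0 else 0.0
        new_col = col * scale
        for idx, t in targets.items():
            new_col[idx] = t
        pos[j] = new_col
    return pos, neg


def _draw_flanks(rng: np.random.Generator, dists: np.ndarray, n: int) -> np.ndarray:
    """Draw n windows' flank indices, shape (n, 2*xi), columns i.i.d."""
    ncols = dists.shape[0]
    out = np.empty((n, ncols), dtype=np.intp)
    for j in range(ncols):
        out[:, j] = rng.choice(21, size=n, p=dists[j])
    return out


def _apply_terminal_padding(
    rng: np.random.Generator, flanks: np.ndarray, xi: int, prob: float
) -> None:
    """Overwrite an X-run at one window end with probability ``prob``."""
    x_idx = 20  # X is code 21 → 0-based index 20
    n = flanks.shape[0]
    hit = rng.random(n) < prob
    sides = rng.integers(0, 2, size=n)
    lengths = rng.integers(1, xi + 1, size=n)
    for i in np.nonzero(hit)[0]:
        k = int(lengths[i])
        if sides[i] == 0:
            flanks[i, :k] = x_idx  # N-terminal run
        else:
            flanks[i, 2 * xi - k :] = x_idx  # C-terminal run


def _flanks_to_window(
    flanks_row: np.ndarray, xi: int, protein_id: str, site: int, label: str
) -> PeptideWindow:
    syms = DEFAULT_ALPHABET.symbols
    left = "".join(syms[i] for i in flanks_row[:xi])
    right = "".join(syms[i] for i in flanks_row[xi:])
    return PeptideWindow(
        protein_id=protein_id, site=site, residues=left + "C" + right, xi=xi, label=label
    )


def generate_benchmark(spec: SyntheticSpec) -> tuple[list[PeptideWindow], list[PeptideWindow]]:
    """Draw the labeled benchmark: (positives, negatives).

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    pos_dists, neg_dists = _column_distributions(spec)
    pos_flanks = _draw_flanks(rng, pos_dists, spec.n_pos)
    neg_flanks = _draw_flanks(rng, neg_dists, spec.n_neg)
    _apply_terminal_padding(rng, pos_flanks, spec.xi, spec.terminal_pad_prob)
    _apply_terminal_padding(rng, neg_flanks, spec.xi, spec.terminal_pad_prob)

    positives: list[PeptideWindow] = []
    negatives: list[PeptideWindow] = []
    per_protein_count: dict[str, int] = {}
    total = spec.n_pos + spec.n_neg
    for i in range(total):
        pid = f"SYNP{i % spec.n_proteins:04d}"
        occ = per_protein_count.get(pid, 0)
        per_protein_count[pid] = occ + 1
        site = spec.xi + 1 + occ * (2 * spec.xi + 1)
        if i < spec.n_pos:
            positives.append(
                _flanks_to_window(pos_flanks[i], spec.xi, pid, site, "positive")
            )
        else:
            negatives.append(
                _flanks_to_window(neg_flanks[i - spec.n_pos], spec.xi, pid, site, "negative")
            )
    return positives, negatives


def generate_proteins(
    spec: SyntheticSpec,
    n_proteins: int,
    sites_per_protein: int = 1,
    length: int = 300,
    max_retries: int = 100,
) -> tuple[list[ProteinRecord], list[tuple[str, int]]]:
    """Random proteins with planted positive-archetype cysteine windows.

    Returns the records and a truth table of planted ``(protein_id, site)``
    pairs.  Background cysteines occur naturally elsewhere in the sequence.
    Planted windows never overlap; if ``sites_per_protein`` non-overlapping
    centers cannot be placed within ``max_retries`` draws, a
    :class:`~snosite.errors.SyntheticSpecError` is raised.
    """
    xi = spec.xi
    if length < 2 * xi + 1:
        raise SyntheticSpecError(f"protein length {length} cannot hold a {2 * xi + 1}-mer")
    rng = np.random.default_rng([spec.seed, 2])
    pos_dists, _ = _column_distributions(spec)
    bg = spec.background_vector()
    syms = DEFAULT_ALPHABET.symbols
    records: list[ProteinRecord] = []
    truth: list[tuple[str, int]] = []
    for p in range(n_proteins):
        pid = f"SYNQ{p:04d}"
        seq = list(rng.choice(20, size=length, p=bg))
        centers: list[int] = []
        tries = 0
        while len(centers) < sites_per_protein:
            c = int(rng.integers(xi, length - xi))  # 0-based center index
            if all(abs(c - other) > 2 * xi for other in centers):
                centers.append(c)
            else:
                tries += 1
                if tries > max_retries:
                    raise SyntheticSpecError(
                        f"could not place {sites_per_protein} non-overlapping sites "
                        f"in a length-{length} protein"
                    )
        for c in sorted(centers):
            flanks = _draw_flanks(rng, pos_dists, 1)[0]
            for k in range(xi):
                seq[c - xi + k] = int(flanks[k])
            seq[c] = 1  # 'C' has 0-based index 1
            for k in range(xi):
                seq[c + 1 + k] = int(flanks[xi + k])
            truth.append((pid, c + 1))
        records.append(ProteinRecord(id=pid, sequence="".join(syms[i] for i in seq)))
    return records, truth
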