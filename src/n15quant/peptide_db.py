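"""Paired unlabeled / 15N peptide-mass databases built from a proteome.

An in-silico tryptic digest of the proteome (plus reversed-protein decoys)
yields, for every peptide, its unlabeled monoisotopic mass, its fully
15N-labeled mass (``+ N x 0.99703489341`` Da where ``N`` is the peptide's
nitrogen count) and its nitrogen count.  Two mass-sorted views of the same
entries -- one indexed by the unlabeled mass, one by the labeled mass -- are
what the pairing and search stages query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from pyteomics import fasta as _pfasta

from .constants import (
    AMINO_ACIDS,
    CARBAMIDOMETHYL_MASS,
    DELTA_15N,
    RESIDUE_MASS,
    RESIDUE_NITROGENS,
    WATER_MASS,
)

#: Default fixed modifications: carbamidomethyl on cysteine.
DEFAULT_FIXED_MODS: dict[str, float] = {"C": CARBAMIDOMETHYL_MASS}

UNLABELED = "unlabeled"
LABELED = "labeled"


def _validate_sequence(sequence: str, extra_residues: str = "") -> None:
    if not sequence:
        raise ValueError("empty peptide/protein sequence")
    allowed = set(AMINO_ACIDS) | set(extra_residues)
    for i, aa in enumerate(sequence):
        if aa not in allowed:
            raise ValueError(f"unknown residue {aa!r} at position {i} in sequence")


def nitrogen_count(sequence: str) -> int:
    """Total nitrogen atoms of a peptide (backbone + side chains)."""
    _validate_sequence(sequence)
    return sum(RESIDUE_NITROGENS[aa] for aa in sequence)


def monoisotopic_mass(
    sequence: str,
    labeled: bool = False,
    fixed_mods: dict[str, float] | None = None,
) -> float:
    """Neutral monoisotopic mass; labeled adds ``N x delta_15N``.

    ``fixed_mods`` maps residue letters to mass deltas applied at every
    occurrence.  Modification mass never contributes to the labeling shift:
    fixed modifications are introduced chemically after harvest, so their
    nitrogen is always light.
    """
    _validate_sequence(sequence)
    mods = DEFAULT_FIXED_MODS if fixed_mods is None else fixed_mods
    m = sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS
    m += sum(mods.get(aa, 0.0) for aa in sequence)
    if labeled:
        m += nitrogen_count(sequence) * DELTA_15N
    return m


@dataclass(frozen=True)
class DigestParams:
    """Digestion and fixed-modification settings.

    cleave_pattern follows the usual trypsin convention: cut C-terminal to
    K or R unless the next residue is proline.
    """

    cleave_pattern: str = r"(?<=[KR])(?!P)"
    max_missed: int = 1
    min_len: int = 6
    max_len: int = 50
    fixed_mods: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FIXED_MODS))


def digest_protein(
    sequence: str,
    max_missed: int,
    min_len: int,
    max_len: int,
    cleave_pattern: str = r"(?<=[KR])(?!P)",
) -> list[str]:
    """All cleavage products with up to ``max_missed`` missed cleavages.

    Deterministic order: by start position along the protein, then by the
    number of missed cleavages.
    """
    _validate_sequence(sequence)
    fragments = [f for f in re.split(cleave_pattern, sequence) if f]
    peptides: list[str] = []
    for start in range(len(fragments)):
        pep = ""
        for missed in range(max_missed + 1):
            if start + missed >= len(fragments):
                break
            pep += fragments[start + missed]
            if min_len <= len(pep) <= max_len:
                peptides.append(pep)
    return peptides


@dataclass(frozen=True)
class PeptideEntry:
    """A digested peptide with both channel masses and its nitrogen count."""

    sequence: str
    mass_unlabeled: float
    mass_labeled: float
    nitrogen_count: int
    proteins: frozenset[str]
    missed_cleavages: int
    is_decoy: bool

    def indexed_mass(self, label_state: str) -> float:
        return self.mass_labeled if label_state == LABELED else self.mass_unlabeled


class PeptideDatabase:
    """Mass-sorted, binary-searchable collection of :class:`PeptideEntry`.

    ``label_state`` selects which of the two masses indexes the entries;
    the unlabeled and labeled databases share the identical peptide set.
    """

    def __init__(self, entries: Iterable[PeptideEntry], label_state: str,
                 digest_params: DigestParams | None = None):
        if label_state not in (UNLABELED, LABELED):
            raise ValueError(f"label_state must be {UNLABELED!r} or {LABELED!r}")
        self.label_state = label_state
        self.digest_params = digest_params or DigestParams()
        self.entries: list[PeptideEntry] = sorted(
            entries, key=lambda e: (e.indexed_mass(label_state), e.sequence, e.is_decoy)
        )
        self._masses = np.array(
            [e.indexed_mass(label_state) for e in self.entries], dtype=float
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PeptideEntry]:
        return iter(self.entries)

    def query_mass(self, mass: float, tol_ppm: float) -> list[PeptideEntry]:
        """Entries whose indexed mass lies within ``tol_ppm`` of ``mass``,
        sorted by absolute mass deviation."""
        if mass <= 0 or tol_ppm <= 0:
            raise ValueError("mass and tol_ppm must be positive")
        tol = mass * tol_ppm * 1e-6
        lo = int(np.searchsorted(self._masses, mass - tol, side="left"))
        hi = int(np.searchsorted(self._masses, mass + tol, side="right"))
        hits = self.entries[lo:hi]
        return sorted(hits, key=lambda e: (abs(e.indexed_mass(self.label_state) - mass),
                                           e.sequence, e.is_decoy))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": [e.sequence for e in self.entries],
                "mass_unlabeled": [e.mass_unlabeled for e in self.entries],
                "mass_labeled": [e.mass_labeled for e in self.entries],
                "nitrogen_count": [e.nitrogen_count for e in self.entries],
                "proteins": [";".join(sorted(e.proteins)) for e in self.entries],
                "missed_cleavages": [e.missed_cleavages for e in self.entries],
                "is_decoy": [e.is_decoy for e in self.entries],
            }
        )


def _parse_accession(header: str) -> str:
    # UniProtKB style "sp|P12345|NAME ..." -> P12345; otherwise first token.
    token = header.split()[0]
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA proteome into ``(accession, sequence)`` records."""
    records: list[tuple[str, str]] = []
    with _pfasta.read(str(path)) as reader:
        for i, (header, seq) in enumerate(reader):
            seq = seq.strip().upper()
            if not seq:
                raise ValueError(f"malformed FASTA record {i}: empty sequence")
            records.append((_parse_accession(header), seq))
    if not records:
        raise ValueError("empty FASTA: no protein records found")
    return records


def _digest_records(
    records: Sequence[tuple[str, str]], params: DigestParams, is_decoy: bool
) -> dict[str, PeptideEntry]:
    by_sequence: dict[str, PeptideEntry] = {}
    for acc, seq in records:
        fragments = [f for f in re.split(params.cleave_pattern, seq) if f]
        for start in range(len(fragments)):
            pep = ""
            for missed in range(params.max_missed + 1):
                if start + missed >= len(fragments):
                    break
                pep += fragments[start + missed]
                if not (params.min_len <= len(pep) <= params.max_len):
                    continue
                prev = by_sequence.get(pep)
                if prev is None:
                    n = nitrogen_count(pep)
                    mu = monoisotopic_mass(pep, labeled=False, fixed_mods=params.fixed_mods)
                    by_sequence[pep] = PeptideEntry(
                        sequence=pep,
                        mass_unlabeled=mu,
                        mass_labeled=mu + n * DELTA_15N,
                        nitrogen_count=n,
                        proteins=frozenset({acc}),
                        missed_cleavages=missed,
                        is_decoy=is_decoy,
                    )
                else:
                    by_sequence[pep] = replace(
                        prev,
                        proteins=prev.proteins | {acc},
                        missed_cleavages=min(prev.missed_cleavages, missed),
                    )
    return by_sequence


def build_databases(
    proteome: str | Path | Sequence[tuple[str, str]],
    digest_params: DigestParams | None = None,
    decoy_prefix: str = "rev_",
) -> tuple[PeptideDatabase, PeptideDatabase]:
    """Digest a proteome into the (unlabeled, labeled) database pair.

    ``proteome`` is a FASTA path or a list of ``(accession, sequence)``
    records.  Decoys come from whole-protein sequence reversal before
    digestion and are concatenated with the targets in both databases.
    Duplicate peptide sequences are merged, unioning their protein sets.
    """
    params = digest_params or DigestParams()
    if isinstance(proteome, (str, Path)):
        records = read_fasta(proteome)
    else:
        records = list(proteome)
        if not records:
            raise ValueError("empty proteome")
    for acc, seq in records:
        _validate_sequence(seq)

    decoy_records = [(decoy_prefix + acc, seq[::-1]) for acc, seq in records]
    targets = _digest_records(records, params, is_decoy=False)
    decoys = _digest_records(decoy_records, params, is_decoy=True)
    entries = list(targets.values()) + list(decoys.values())
    if not entries:
        raise ValueError("digest produced no peptides within the length bounds")
    return (
        PeptideDatabase(entries, UNLABELED, params),
        PeptideDatabase(entries, LABELED, params),
    )


def peptide_to_protein_map(db: PeptideDatabase) -> dict[str, frozenset[str]]:
    """Target-peptide sequence -> parent protein accessions."""
    return {e.sequence: e.proteins for e in db.entries if not e.is_decoy}


def write_database_tsv(db: PeptideDatabase, path: str | Path) -> None:
    db.to_frame().to_csv(path, sep="\t", index=False)
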