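"""Sequence-level descriptors of short peptides.

Computes the quantities used to characterize peptides prior to multi-chain
simulation: the grand average of hydropathy (GRAVY, Kyte–Doolittle), the
Henderson–Hasselbalch net charge at a given pH (with configurable pKa set
and terminal modifications), and the cubic periodic-box side length that
realizes a target molar concentration for a given number of chains.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .constants import AVOGADRO
from .errors import InvalidSequenceError, PeptideTableError

logger = logging.getLogger(__name__)

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

N_TERM_KINDS = ("free", "acetyl")
C_TERM_KINDS = ("free-acid", "amide")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed peptide tables)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide as a unit of study: sequence, termini, experimental concentration."""

    name: str
    sequence: str
    n_term: str = "free"
    c_term: str = "free-acid"
    concentration: float = 1.0  # mM
    n_chains: int = 8

    def __post_init__(self):
        if not self.sequence:
            raise InvalidSequenceError("empty sequence")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise InvalidSequenceError(
                f"non-canonical residue letter(s) {sorted(bad)} in {self.name!r}"
            )
        if self.n_term not in N_TERM_KINDS:
            raise ValueError(f"n_term must be one of {N_TERM_KINDS}")
        if self.c_term not in C_TERM_KINDS:
            raise ValueError(f"c_term must be one of {C_TERM_KINDS}")
        if not self.concentration > 0:
            raise ValueError("concentration must be positive")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydropathy indices, complete over the 20 canonical residues."""

    values: dict = field(default_factory=lambda: dict(_KYTE_DOOLITTLE))

    def __post_init__(self):
        missing = CANONICAL_RESIDUES - set(self.values)
        if missing:
            raise ValueError(f"scale incomplete, missing {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


#: Kyte–Doolittle scale (the default for GRAVY).
KYTE_DOOLITTLE = HydropathyScale()


@dataclass(frozen=True)
class PkaSet:
    """pKa values for the ionizable side chains and free termini.

    ``acidic`` groups release a proton (carry charge -1 when deprotonated);
    ``basic`` groups bind one (charge +1 when protonated).
    """

    acidic: dict = field(
        default_factory=lambda: {"D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.07}
    )
    basic: dict = field(default_factory=lambda: {"H": 6.0, "K": 10.53, "R": 12.48})
    n_terminus: float = 9.0
    c_terminus: float = 3.6

    def __post_init__(self):
        for pka in [*self.acidic.values(), *self.basic.values(),
                    self.n_terminus, self.c_terminus]:
            if not 0 < pka < 14:
                raise ValueError(f"pKa {pka} outside (0, 14)")


DEFAULT_PKA = PkaSet()


def compute_gravy(record: PeptideRecord | str,
                  scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathy: mean scale value over the residues.

    Terminal modifications do not enter; the value depends only on
    composition.
    """
    seq = record.sequence if isinstance(record, PeptideRecord) else record
    if not seq:
        raise InvalidSequenceError("empty sequence")
    total = 0.0
    for aa in seq:
        try:
            total += scale[aa]
        except KeyError:
            raise InvalidSequenceError(f"unknown residue letter {aa!r}") from None
    return total / len(seq)


def compute_net_charge(record: PeptideRecord, pka: PkaSet = DEFAULT_PKA,
                       pH: float = 7.0) -> float:
    """Henderson–Hasselbalch net charge in elementary charges.

    Sums ``1/(1+10^(pH-pKa))`` over basic groups and ``-1/(1+10^(pKa-pH))``
    over acidic groups. The terminal amine contributes only for a free
    N-terminus, the terminal carboxyl only for a free-acid C-terminus.
    """
    if not 0 < pH < 14:
        raise ValueError("pH must lie in (0, 14)")
    charge = 0.0
    for aa in record.sequence:
        if aa in pka.basic:
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka.basic[aa]))
        elif aa in pka.acidic:
            charge -= 1.0 / (1.0 + 10.0 ** (pka.acidic[aa] - pH))
    if record.n_term == "free":
        charge += 1.0 / (1.0 + 10.0 ** (pH - pka.n_terminus))
    if record.c_term == "free-acid":
        charge -= 1.0 / (1.0 + 10.0 ** (pka.c_terminus - pH))
    return charge


def box_side_for_concentration(concentration: float, n_chains: int) -> float:
    """Cubic box side (angstrom) realizing ``concentration`` (mM) for ``n_chains``.

    side = (n / (C * N_A))^(1/3), with the volume converted from liters
    (1 L = 1e27 cubic angstrom).
    """
    if not concentration > 0:
        raise ValueError("concentration must be positive")
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    volume_A3 = n_chains / (concentration * 1e-3 * AVOGADRO) * 1e27
    return volume_A3 ** (1.0 / 3.0)


_TABLE_COLUMNS = ("name", "sequence", "n_term", "c_term", "concentration_mM")


def load_peptide_table(path: str | Path, n_chains: int = 8) -> list[PeptideRecord]:
    """Read peptide records from a delimited table or a FASTA file.

    Tables need a header with the columns ``name sequence n_term c_term
    concentration_mM``. FASTA records default to free termini and 1 mM.
    """
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".faa"):
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            records.append(PeptideRecord(name=rec.id, sequence=str(rec.seq),
                                         n_chains=n_chains))
        if not records:
            logger.warning("no records found in %s", path)
        return records

    if path.stat().st_size == 0:
        logger.warning("empty peptide table %s", path)
        return []
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise PeptideTableError(f"missing column(s) {sorted(missing)}")
    if df.empty:
        logger.warning("empty peptide table %s", path)
        return []
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = str(row["name"])
        if name in seen:
            raise PeptideTableError(f"duplicate name {name!r}", row=int(i))
        seen.add(name)
        try:
            conc = float(row["concentration_mM"])
        except (TypeError, ValueError):
            raise PeptideTableError(
                f"unparsable concentration {row['concentration_mM']!r}", row=int(i)
            ) from None
        try:
            records.append(
                PeptideRecord(
                    name=name,
                    sequence=str(row["sequence"]).strip(),
                    n_term=str(row["n_term"]).strip(),
                    c_term=str(row["c_term"]).strip(),
                    concentration=conc,
                    n_chains=n_chains,
                )
            )
        except (InvalidSequenceError, ValueError) as exc:
            raise PeptideTableError(str(exc), row=int(i)) from exc
    return records


def reference_peptides(n_chains: int = 8) -> list[PeptideRecord]:
    """The 20-peptide study set bundled with the package."""
    from importlib.resources import files

    path = files("pepagg").joinpath("data/peptides.tsv")
    return load_peptide_table(Path(str(path)), n_chains=n_chains)


def descriptor_table(records: list[PeptideRecord], pH: float = 7.0,
                     pka: PkaSet = DEFAULT_PKA,
                     scale: HydropathyScale = KYTE_DOOLITTLE) -> pd.DataFrame:
    """Tabulate name, length, charge, GRAVY, concentration and box side."""
    rows = []
    for rec in records:
        rows.append({
            "name": rec.name,
            "n_residues": len(rec),
            "sequence": rec.sequence,
            "net_charge": round_half_away(compute_net_charge(rec, pka, pH), 1),
            "gravy": round_half_away(compute_gravy(rec, scale), 3),
            "concentration_mM": rec.concentration,
            "box_side_A": round_half_away(
                box_side_for_concentration(rec.concentration, rec.n_chains), 1
            ),
        })
    return pd.DataFrame(rows)
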