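"""Restriction enzyme definitions.

A small built-in table of common commercially available enzymes (IUPAC
recognition sequences with supplier tags) is shipped for convenience;
users can supply their own table as TSV: ``name<TAB>recognition<TAB>
supplier,supplier,...``.  Supplier filtering is a plain tag match, not a
live catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._dna import IUPAC_BASES
from .errors import FormatError


@dataclass(frozen=True)
class EnzymeDef:
    name: str
    recognition: str  # IUPAC DNA
    supplier_tags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.recognition:
            raise FormatError(f"enzyme {self.name}: empty recognition sequence")
        for letter in self.recognition.upper():
            if letter not in IUPAC_BASES:
                raise FormatError(
                    f"enzyme {self.name}: invalid IUPAC letter {letter!r}"
                )

    @property
    def site_length(self) -> int:
        return len(self.recognition)


_BUILTIN: list[tuple[str, str, str]] = [
    # name, recognition (IUPAC), suppliers
    ("EcoRI", "GAATTC", "NEB,Thermo,Promega,Takara"),
    ("BamHI", "GGATCC", "NEB,Thermo,Promega,Takara"),
    ("HindIII", "AAGCTT", "NEB,Thermo,Promega,Takara"),
    ("NotI", "GCGGCCGC", "NEB,Thermo,Promega"),
    ("XhoI", "CTCGAG", "NEB,Thermo,Promega"),
    ("XbaI", "TCTAGA", "NEB,Thermo,Promega"),
    ("SpeI", "ACTAGT", "NEB,Thermo"),
    ("PstI", "CTGCAG", "NEB,Thermo,Promega,Takara"),
    ("SacI", "GAGCTC", "NEB,Thermo,Promega"),
    ("KpnI", "GGTACC", "NEB,Thermo,Promega,Takara"),
    ("SmaI", "CCCGGG", "NEB,Thermo,Promega"),
    ("ApaI", "GGGCCC", "NEB,Thermo,Promega"),
    ("SalI", "GTCGAC", "NEB,Thermo,Promega,Takara"),
    ("ClaI", "ATCGAT", "NEB,Thermo"),
    ("EcoRV", "GATATC", "NEB,Thermo,Promega"),
    ("DraI", "TTTAAA", "NEB,Thermo,Promega"),
    ("SspI", "AATATT", "NEB,Thermo"),
    ("NdeI", "CATATG", "NEB,Thermo"),
    ("NcoI", "CCATGG", "NEB,Thermo,Promega"),
    ("NheI", "GCTAGC", "NEB,Thermo"),
    ("BglII", "AGATCT", "NEB,Thermo,Promega"),
    ("MfeI", "CAATTG", "NEB"),
    ("HpaI", "GTTAAC", "NEB,Thermo,Promega"),
    ("ScaI", "AGTACT", "NEB,Thermo,Promega"),
    ("StuI", "AGGCCT", "NEB,Thermo,Promega"),
    ("PvuII", "CAGCTG", "NEB,Thermo,Promega,Takara"),
    ("AflII", "CTTAAG", "NEB,Thermo"),
    ("AgeI", "ACCGGT", "NEB,Thermo"),
    ("AvrII", "CCTAGG", "NEB"),
    ("BsrGI", "TGTACA", "NEB,Thermo"),
    ("HincII", "GTYRAC", "NEB,Thermo,Promega"),
    ("AvaI", "CYCGRG", "NEB,Thermo"),
    ("BanI", "GGYRCC", "NEB"),
    ("AccI", "GTMKAC", "NEB,Promega"),
    ("StyI", "CCWWGG", "NEB,Thermo"),
    ("ApoI", "RAATTY", "NEB"),
    ("AluI", "AGCT", "NEB,Thermo,Promega"),
    ("HaeIII", "GGCC", "NEB,Thermo,Promega,Takara"),
    ("MboI", "GATC", "NEB,Thermo"),
    ("MseI", "TTAA", "NEB"),
    ("RsaI", "GTAC", "NEB,Thermo,Promega"),
    ("TaqI", "TCGA", "NEB,Thermo,Promega"),
]


def builtin_enzymes(supplier: str | None = None) -> list[EnzymeDef]:
    """The built-in table, optionally filtered to one supplier tag."""
    out = [
        EnzymeDef(name, rec, tuple(sup.split(",")))
        for name, rec, sup in _BUILTIN
    ]
    if supplier is not None:
        out = [e for e in out if supplier in e.supplier_tags]
    return out


def load_enzyme_table(path: str | Path) -> list[EnzymeDef]:
    """Read a user enzyme table (TSV: name, recognition, suppliers)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"enzyme table not found: {path}")
    out: list[EnzymeDef] = []
    seen: set[str] = set()
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path.name} line {i}: need name and recognition")
        name, rec = fields[0], fields[1].upper()
        if name in seen:
            raise FormatError(f"{path.name} line {i}: duplicate enzyme {name!r}")
        seen.add(name)
        tags = tuple(fields[2].split(",")) if len(fields) > 2 and fields[2] else ()
        out.append(EnzymeDef(name, rec, tags))
    return out
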