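"""Core data types and file I/O for DNA + stable-isotope profiles.

A *DNA profile* is one biopsied individual: genetically identified sex, an
mtDNA control-region haplotype label, and a diploid multi-locus microsatellite
genotype (up to ~17 loci, integer fragment sizes).  An *isotope profile*
carries the same individual's skin δ13C / δ15N values (‰).  Individuals are
stratified three ways: sampling location, habitat class (calving ground vs
migratory corridor) and management unit (e.g. locations pooled into SEA / SWA).

Conventions
-----------
* Alleles are integers; a genotype at a locus is an unordered pair, stored
  sorted.  A locus is either fully typed (two alleles) or absent from the
  genotype map — never half-typed.
* The locus set of a sample collection is the union over individuals.
* Sample tables are delimited text (CSV/TSV) with one ``<locus>_1,<locus>_2``
  column pair per locus.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

HABITATS = ("calving", "migratory")
SEXES = ("F", "M", "unknown")

#: column order of the canonical sample table, before the per-locus pairs
FIXED_COLUMNS = (
    "sample_id",
    "location",
    "habitat",
    "management_unit",
    "sex",
    "haplotype",
    "d13C",
    "d15N",
)


class SampleTableError(ValueError):
    """Malformed sample table (duplicate ids, half-typed loci, bad columns)."""


@dataclass(frozen=True)
class DNAProfile:
    """One individual's DNA profile.

    ``genotype`` maps locus name to a sorted (allele, allele) tuple; untyped
    loci are simply absent.  ``haplotype`` is None when no mtDNA sequence was
    obtained.
    """

    sample_id: str
    location: str
    habitat: str
    management_unit: str
    sex: str = "unknown"
    haplotype: str | None = None
    genotype: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"habitat must be one of {HABITATS}, got {self.habitat!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        geno = {}
        for locus, pair in dict(self.genotype).items():
            if pair is None or len(pair) != 2 or any(a is None for a in pair):
                raise ValueError(
                    f"locus {locus!r} of sample {self.sample_id!r} is half-typed; "
                    "a locus carries exactly two alleles or is absent"
                )
            a, b = int(pair[0]), int(pair[1])
            geno[str(locus)] = (a, b) if a <= b else (b, a)
        object.__setattr__(self, "genotype", geno)

    def typed_loci(self) -> list[str]:
        return sorted(self.genotype)

    def is_heterozygous(self, locus: str) -> bool:
        a, b = self.genotype[locus]
        return a != b


@dataclass(frozen=True)
class IsotopeProfile:
    """Stable-isotope values (‰, vs PDB / air) linked to a DNA profile."""

    sample_id: str
    d13C: float | None = None
    d15N: float | None = None


@dataclass(frozen=True)
class HaplotypeSet:
    """Aligned mtDNA control-region haplotypes: name -> sequence (same length)."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        seqs = {str(k): str(v).upper() for k, v in dict(self.sequences).items()}
        if not seqs:
            raise ValueError("empty haplotype set")
        lengths = {name: len(s) for name, s in seqs.items()}
        if len(set(lengths.values())) > 1:
            bad = ", ".join(f"{n}:{l}" for n, l in sorted(lengths.items()))
            raise ValueError(f"haplotype sequences are not all the same length ({bad})")
        for name, s in seqs.items():
            extra = set(s) - set("ACGTN")
            if extra:
                raise ValueError(f"haplotype {name!r} has non-ACGTN symbols {sorted(extra)}")
        object.__setattr__(self, "sequences", seqs)

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def names(self) -> list[str]:
        return sorted(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]


@dataclass(frozen=True)
class StratificationScheme:
    """Maps each sampling location to its habitat class and management unit.

    Pooling (e.g. VIC+TAS+NSW+QLD -> SEA; SA+WA -> SWA) is expressed by giving
    several locations the same management unit.
    """

    mapping: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        m = {}
        for loc, (hab, mu) in dict(self.mapping).items():
            if hab not in HABITATS:
                raise ValueError(f"location {loc!r}: habitat {hab!r} not in {HABITATS}")
            m[str(loc)] = (hab, str(mu))
        object.__setattr__(self, "mapping", m)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StratificationScheme":
        """Build from {location: {"habitat": ..., "management_unit": ...}} (YAML/JSON)."""
        return cls({loc: (v["habitat"], v["management_unit"]) for loc, v in d.items()})

    def habitat(self, location: str) -> str:
        return self.mapping[location][0]

    def management_unit(self, location: str) -> str:
        return self.mapping[location][1]

    def locations(self) -> list[str]:
        return sorted(self.mapping)


def _split_genotype_columns(header: Sequence[str]) -> list[str]:
    """Return locus names from trailing <locus>_1/<locus>_2 column pairs."""
    allele_cols = [c for c in header if c not in FIXED_COLUMNS]
    if len(allele_cols) % 2:
        raise SampleTableError(
            f"odd number of allele columns ({len(allele_cols)}); "
            "each locus needs a <locus>_1,<locus>_2 pair"
        )
    loci = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise SampleTableError(f"allele columns {c1!r},{c2!r} are not a <locus>_1/<locus>_2 pair")
        loci.append(c1[:-2])
    return loci


def read_sample_table(
    path: str | Path,
    missing_codes: Iterable[str] = ("", "NA", "0"),
    delimiter: str | None = None,
) -> tuple[list[DNAProfile], list[IsotopeProfile]]:
    """Read a delimited sample table into DNA + isotope profiles.

    Parameters
    ----------
    path:
        CSV/TSV file with header.  Columns: the fixed block
        ``sample_id,location,habitat,management_unit,sex,haplotype,d13C,d15N``
        followed by one ``<locus>_1,<locus>_2`` pair per microsatellite locus.
    missing_codes:
        Cell values normalised to "missing" ("0" is the conventional
        microsatellite missing-allele code and is included by default).
    delimiter:
        Explicit delimiter; by default "\\t" for .tsv files, "," otherwise.

    Raises
    ------
    SampleTableError
        On duplicate sample ids, odd allele-column counts, or half-typed loci
        (one allele missing at a locus); the error names the row and locus.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    missing = {str(c) for c in missing_codes}

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SampleTableError(f"{path}: empty file")
        loci = _split_genotype_columns(reader.fieldnames)
        for col in ("sample_id", "location", "habitat", "management_unit"):
            if col not in reader.fieldnames:
                raise SampleTableError(f"{path}: required column {col!r} absent")

        profiles: list[DNAProfile] = []
        isotopes: list[IsotopeProfile] = []
        seen: set[str] = set()
        for row_no, row in enumerate(reader, start=2):
            sid = (row["sample_id"] or "").strip()
            if not sid:
                raise SampleTableError(f"row {row_no}: blank sample_id")
            if sid in seen:
                raise SampleTableError(f"row {row_no}: duplicate sample_id {sid!r}")
            seen.add(sid)

            def cell(col: str) -> str | None:
                v = (row.get(col) or "").strip()
                return None if v in missing else v

            geno = {}
            for locus in loci:
                a, b = cell(f"{locus}_1"), cell(f"{locus}_2")
                if (a is None) != (b is None):
                    raise SampleTableError(
                        f"row {row_no} (sample {sid!r}): locus {locus!r} is half-typed"
                    )
                if a is not None:
                    geno[locus] = (int(a), int(b))

            profiles.append(
                DNAProfile(
                    sample_id=sid,
                    location=cell("location") or "",
                    habitat=cell("habitat") or "calving",
                    management_unit=cell("management_unit") or "",
                    sex=cell("sex") or "unknown",
                    haplotype=cell("haplotype"),
                    genotype=geno,
                )
            )
            c, n = cell("d13C"), cell("d15N")
            if c is not None or n is not None:
                isotopes.append(
                    IsotopeProfile(
                        sample_id=sid,
                        d13C=float(c) if c is not None else None,
                        d15N=float(n) if n is not None else None,
                    )
                )
    return profiles, isotopes


def write_sample_table(
    path: str | Path,
    profiles: Sequence[DNAProfile],
    isotopes: Sequence[IsotopeProfile] = (),
    delimiter: str | None = None,
) -> None:
    """Write profiles to the canonical sample-table format (round-trips with
    :func:`read_sample_table`).  Missing cells are left empty."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    loci = locus_union(profiles)
    iso = {p.sample_id: p for p in isotopes}
    header = list(FIXED_COLUMNS) + [f"{l}_{i}" for l in loci for i in (1, 2)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(header)
        for p in profiles:
            ip = iso.get(p.sample_id)
            row = [
                p.sample_id,
                p.location,
                p.habitat,
                p.management_unit,
                p.sex,
                p.haplotype or "",
                "" if ip is None or ip.d13C is None else repr(ip.d13C),
                "" if ip is None or ip.d15N is None else repr(ip.d15N),
            ]
            for l in loci:
                pair = p.genotype.get(l)
                row += ["", ""] if pair is None else [pair[0], pair[1]]
            w.writerow(row)


def read_haplotype_fasta(path: str | Path) -> HaplotypeSet:
    """Read aligned haplotype sequences from FASTA.

    All records must have equal length; offending records are listed otherwise.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    lengths = {r.id: len(r.seq) for r in records}
    if len(set(lengths.values())) > 1:
        ref = len(records[0].seq)  # first record sets the expected length
        bad = [f"{n} ({l} bp)" for n, l in lengths.items() if l != ref]
        raise ValueError(f"{path}: unequal record lengths, offending records: {', '.join(bad)}")
    names = [r.id for r in records]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate record names")
    return HaplotypeSet({r.id: str(r.seq) for r in records})


def write_haplotype_fasta(path: str | Path, hapset: HaplotypeSet) -> None:
    with open(path, "w") as fh:
        for name in hapset.names:
            fh.write(f">{name}\n{hapset[name]}\n")


def locus_union(profiles: Sequence[DNAProfile]) -> list[str]:
    """Union of typed loci over a profile collection, sorted."""
    loci: set[str] = set()
    for p in profiles:
        loci.update(p.genotype)
    return sorted(loci)


def assign_strata(
    profiles: Sequence[DNAProfile],
    scheme: StratificationScheme | None,
    level: str,
) -> dict[str, list[DNAProfile]]:
    """Partition profiles at a stratification level.

    ``level`` is one of ``location``, ``habitat``, ``management_unit``.  When a
    scheme is given, habitat and management unit are looked up from each
    profile's location (every location must be mapped); otherwise the labels
    carried on the profiles are used.  Returns ``{stratum: [profiles]}`` —
    disjoint groups covering the input.
    """
    if level not in ("location", "habitat", "management_unit"):
        raise ValueError(f"unknown stratification level {level!r}")
    out: dict[str, list[DNAProfile]] = {}
    for p in profiles:
        if level == "location":
            key = p.location
        elif scheme is not None:
            if p.location not in scheme.mapping:
                raise KeyError(f"location {p.location!r} not mapped by the stratification scheme")
            key = scheme.habitat(p.location) if level == "habitat" else scheme.management_unit(p.location)
        else:
            key = p.habitat if level == "habitat" else p.management_unit
        out.setdefault(key, []).append(p)
    return dict(sorted(out.items()))


def load_scheme(path: str | Path) -> StratificationScheme:
    """Load a stratification scheme from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        d = json.loads(text)
    else:
        import yaml

        d = yaml.safe_load(text)
    return StratificationScheme.from_dict(d)
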