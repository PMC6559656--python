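"""File I/O: native variant-table TSV, VCF 4.2 interop, Newick, JSON reports.

Native dialect (tab-separated, header row)::

    id  rsid  position  class  alleles  SUBJ1  SUBJ2 ...
    m1  rs1   -2315     SNP    A,G      A/G    .

Calls are unordered ``a1/a2`` pairs, ``.`` for missing.  A phased table uses
``a1|a2`` and carries a ``#phased`` pragma.  An optional ``#phenotype`` pragma
line labels subjects case/control.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Optional, Sequence, TextIO, Union

from . import __version__
from .core import (
    GenotypeMatrix,
    HaplotypeSet,
    HaplotypeSource,
    Marker,
    Phenotype,
    VarClass,
    tss_to_contig,
    contig_to_tss,
)

__all__ = [
    "FormatError",
    "read_variant_table",
    "write_variant_table",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_vcf",
    "write_vcf",
    "write_newick",
    "write_report",
]

_FIXED_COLS = ["id", "rsid", "position", "class", "alleles"]


class FormatError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


def _open(path_or_handle, mode: str):
    if hasattr(path_or_handle, "read") or hasattr(path_or_handle, "write"):
        return path_or_handle, False
    return open(path_or_handle, mode), True


def write_variant_table(
    path,
    markers: Sequence[Marker],
    calls: GenotypeMatrix,
) -> None:
    """Write markers + unordered diploid calls in the native TSV dialect."""
    fh, close = _open(path, "w")
    try:
        fh.write("\t".join(_FIXED_COLS + list(calls.subjects)) + "\n")
        if calls.phenotype:
            labels = [
                calls.phenotype[s].value if s in calls.phenotype else "-"
                for s in calls.subjects
            ]
            fh.write("#phenotype\t-\t-\t-\t-\t" + "\t".join(labels) + "\n")
        by_id = {mk.id: mk for mk in markers}
        for j, mid in enumerate(calls.marker_ids):
            mk = by_id[mid]
            row = [
                mk.id,
                mk.rsid or ".",
                str(mk.position),
                mk.var_class.value,
                ",".join(mk.alleles),
            ]
            for i in range(calls.n_subjects):
                call = calls.calls[i][j]
                row.append("." if call is None else f"{call[0]}/{call[1]}")
            fh.write("\t".join(row) + "\n")
    finally:
        if close:
            fh.close()


def _parse_header(line: str, lineno: int) -> list[str]:
    cols = line.rstrip("\n").split("\t")
    if cols[: len(_FIXED_COLS)] != _FIXED_COLS:
        raise FormatError(
            f"header must start with {_FIXED_COLS}, got {cols[:5]}", lineno
        )
    return cols[len(_FIXED_COLS) :]


def read_variant_table(path) -> tuple[list[Marker], GenotypeMatrix]:
    """Read the native TSV dialect; raises :class:`FormatError` on bad lines."""
    fh, close = _open(path, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    if not lines:
        raise FormatError("empty file", 1)
    subjects = _parse_header(lines[0], 1)
    phenotype: Optional[dict[str, Phenotype]] = None
    markers: list[Marker] = []
    columns: list[list[Optional[tuple[str, str]]]] = []
    seen_ids: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if fields[0] == "#phenotype":
            phenotype = {}
            for s, lab in zip(subjects, fields[len(_FIXED_COLS) :]):
                if lab != "-":
                    try:
                        phenotype[s] = Phenotype(lab)
                    except ValueError:
                        raise FormatError(f"bad phenotype label {lab!r}", lineno)
            continue
        if line.startswith("#"):
            continue
        if len(fields) != len(_FIXED_COLS) + len(subjects):
            raise FormatError(
                f"expected {len(_FIXED_COLS) + len(subjects)} fields, "
                f"got {len(fields)}",
                lineno,
            )
        mid, rsid, pos_s, class_s, alleles_s = fields[:5]
        if mid in seen_ids:
            raise FormatError(f"duplicate marker id {mid!r}", lineno)
        seen_ids.add(mid)
        try:
            position = int(pos_s)
        except ValueError:
            raise FormatError(f"bad position {pos_s!r}", lineno)
        try:
            var_class = VarClass(class_s)
        except ValueError:
            raise FormatError(f"unknown class {class_s!r}", lineno)
        alleles = tuple(alleles_s.split(","))
        try:
            marker = Marker(
                id=mid,
                rsid=None if rsid == "." else rsid,
                position=position,
                var_class=var_class,
                alleles=alleles,
            )
        except ValueError as exc:
            raise FormatError(str(exc), lineno)
        col: list[Optional[tuple[str, str]]] = []
        for s, cell in zip(subjects, fields[5:]):
            if cell == ".":
                col.append(None)
                continue
            sep = "/" if "/" in cell else "|"
            parts = cell.split(sep)
            if len(parts) != 2:
                raise FormatError(f"bad call {cell!r} for subject {s}", lineno)
            if not set(parts) <= set(alleles):
                raise FormatError(
                    f"call {cell!r} uses alleles outside {alleles}", lineno
                )
            col.append((parts[0], parts[1]))
        markers.append(marker)
        columns.append(col)
    calls = GenotypeMatrix(
        subjects=subjects,
        marker_ids=[m.id for m in markers],
        calls=[[columns[j][i] for j in range(len(markers))]
               for i in range(len(subjects))],
        phenotype=phenotype,
    )
    return markers, calls


def write_haplotype_table(
    path,
    markers: Sequence[Marker],
    haps: HaplotypeSet,
    phenotype: Optional[dict[str, Phenotype]] = None,
) -> None:
    """Phased variant of the native dialect (``a1|a2``, ``#phased`` pragma)."""
    fh, close = _open(path, "w")
    try:
        subjects = haps.subjects
        fh.write("\t".join(_FIXED_COLS + subjects) + "\n")
        fh.write("#phased\n")
        if phenotype:
            labels = [
                phenotype[s].value if s in phenotype else "-" for s in subjects
            ]
            fh.write("#phenotype\t-\t-\t-\t-\t" + "\t".join(labels) + "\n")
        by_subject: dict[str, list[tuple[str, ...]]] = {}
        for h, s in zip(haps.haplotypes, haps.subject_of):
            by_subject.setdefault(s, []).append(h)
        by_id = {mk.id: mk for mk in markers}
        for j, mid in enumerate(haps.marker_ids):
            mk = by_id[mid]
            row = [
                mk.id,
                mk.rsid or ".",
                str(mk.position),
                mk.var_class.value,
                ",".join(mk.alleles),
            ]
            for s in subjects:
                h1, h2 = by_subject[s]
                row.append(f"{h1[j]}|{h2[j]}")
            fh.write("\t".join(row) + "\n")
    finally:
        if close:
            fh.close()


def read_haplotype_table(path) -> tuple[list[Marker], HaplotypeSet]:
    """Read a ``#phased`` native table back into a :class:`HaplotypeSet`."""
    markers, gm = read_variant_table(path)
    # re-read preserving order: read_variant_table sorts pairs, so parse again
    fh, close = _open(path, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    subjects = _parse_header(lines[0], 1)
    vectors: dict[str, list[list[str]]] = {s: [[], []] for s in subjects}
    for line in lines[1:]:
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        for s, cell in zip(subjects, fields[5:]):
            a1, a2 = cell.split("|") if "|" in cell else cell.split("/")
            vectors[s][0].append(a1)
            vectors[s][1].append(a2)
    haplotypes: list[tuple[str, ...]] = []
    subject_of: list[str] = []
    for s in subjects:
        haplotypes.append(tuple(vectors[s][0]))
        haplotypes.append(tuple(vectors[s][1]))
        subject_of.extend([s, s])
    haps = HaplotypeSet(
        haplotypes=haplotypes,
        subject_of=subject_of,
        marker_ids=[m.id for m in markers],
        source=HaplotypeSource.INPUT,
    )
    return markers, haps


def write_vcf(
    path,
    markers: Sequence[Marker],
    calls: GenotypeMatrix,
    offset: int,
    contig: str = "region",
    phased: bool = False,
) -> None:
    """Export to VCF 4.2; TSS-relative positions are mapped to 1-based contig
    coordinates via ``offset`` (the contig coordinate of TSS +1).

    Repeat-class alleles (integer labels) are written as symbolic ALTs and the
    original labels preserved in INFO/ALLELES so that :func:`read_vcf` round
    trips them.
    """
    fh, close = _open(path, "w")
    sep = "|" if phased else "/"
    try:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=promoterpop-{__version__}\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write(f"##promoterpop_tss_offset={offset}\n")
        fh.write('##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">\n')
        fh.write(
            '##INFO=<ID=ALLELES,Number=.,Type=String,'
            'Description="Original allele labels">\n'
        )
        fh.write('##INFO=<ID=TSSPOS,Number=1,Type=Integer,'
                 'Description="TSS-relative position">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(calls.subjects)
            + "\n"
        )
        by_id = {mk.id: mk for mk in markers}
        order = sorted(
            range(len(calls.marker_ids)),
            key=lambda j: by_id[calls.marker_ids[j]].position,
        )
        for j in order:
            mk = by_id[calls.marker_ids[j]]
            pos = tss_to_contig(mk.position, offset)

            def vcf_allele(a: str, is_ref: bool) -> str:
                if all(c in "ACGTN" for c in a) and a:
                    return a
                return "N" if is_ref else f"<{a}>"

            ref = vcf_allele(mk.alleles[0], True)
            alts = [vcf_allele(a, False) for a in mk.alleles[1:]]
            info = (
                f"VC={mk.var_class.value};"
                f"ALLELES={','.join(mk.alleles)};TSSPOS={mk.position}"
            )
            idx = {a: k for k, a in enumerate(mk.alleles)}
            gts = []
            for i in range(calls.n_subjects):
                call = calls.calls[i][j]
                if call is None:
                    gts.append(f".{sep}.")
                else:
                    gts.append(f"{idx[call[0]]}{sep}{idx[call[1]]}")
            fh.write(
                f"{contig}\t{pos}\t{mk.id}\t{ref}\t{','.join(alts)}\t.\t.\t"
                f"{info}\tGT\t" + "\t".join(gts) + "\n"
            )
    finally:
        if close:
            fh.close()


def read_vcf(path, offset: Optional[int] = None) -> tuple[list[Marker], GenotypeMatrix]:
    """Import an (uncompressed) VCF written by :func:`write_vcf` or any plain
    VCF with GT fields.  ``offset`` overrides the embedded TSS offset."""
    markers: list[Marker] = []
    columns: list[list[Optional[tuple[str, str]]]] = []
    subjects: list[str] = []
    file_offset: Optional[int] = offset
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##promoterpop_tss_offset=") and offset is None:
                file_offset = int(line.split("=", 1)[1])
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                subjects = line.split("\t")[9:]
                continue
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError("VCF record with no samples", lineno)
            pos = int(fields[1])
            mid, ref, alt, info = fields[2], fields[3], fields[4], fields[7]
            info_map = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            if "ALLELES" in info_map:
                alleles = tuple(info_map["ALLELES"].split(","))
            else:
                alleles = tuple(
                    a[1:-1] if a.startswith("<") else a
                    for a in [ref] + alt.split(",")
                )
            if "TSSPOS" in info_map:
                position = int(info_map["TSSPOS"])
            elif file_offset is not None:
                position = contig_to_tss(pos, file_offset)
            else:
                position = pos
            if "VC" in info_map:
                var_class = VarClass(info_map["VC"])
            else:
                lengths = {len(a) for a in alleles}
                if lengths == {1} and len(alleles) == 2:
                    var_class = VarClass.SNP
                elif lengths == {2} and len(alleles) == 2:
                    var_class = VarClass.DNP
                else:
                    var_class = VarClass.INDEL
            try:
                marker = Marker(
                    id=mid if mid != "." else f"m{pos}",
                    position=position,
                    var_class=var_class,
                    alleles=alleles,
                )
            except ValueError as exc:
                raise FormatError(str(exc), lineno)
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            col: list[Optional[tuple[str, str]]] = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_i]
                sep = "|" if "|" in gt else "/"
                parts = gt.split(sep)
                if "." in parts or len(parts) != 2:
                    col.append(None)
                else:
                    col.append((alleles[int(parts[0])], alleles[int(parts[1])]))
            markers.append(marker)
            columns.append(col)
    calls = GenotypeMatrix(
        subjects=subjects,
        marker_ids=[m.id for m in markers],
        calls=[[columns[j][i] for j in range(len(markers))]
               for i in range(len(subjects))],
    )
    return markers, calls


def write_newick(path, newick: str) -> None:
    fh, close = _open(path, "w")
    try:
        fh.write(newick.rstrip("\n") + "\n")
    finally:
        if close:
            fh.close()


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(path, payload: dict, seed: Optional[int] = None,
                 config: Optional[dict] = None) -> None:
    """Write a JSON report stamped with tool version, seed and config hash."""
    doc = {
        "tool": "promoterpop",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    doc.update(payload)
    fh, close = _open(path, "w")
    try:
        json.dump(doc, fh, indent=2, sort_keys=False, default=str)
        fh.write("\n")
    finally:
        if close:
            fh.close()
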