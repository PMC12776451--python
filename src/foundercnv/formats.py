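"""Readers and writers for the pipeline's external formats, plus genetic-map
interpolation.

Coordinate convention: every position read or written is 1-based inclusive,
so an interval ``[start_bp, end_bp]`` has ``size_bp = end_bp - start_bp + 1``.
Genetic distances are carried in Morgans internally (the Gamma-method rate
``tau`` is per Morgan); centiMorgans appear only at file boundaries.

Formats handled here:

* CNV call tables — TSV with header ``sample chrom start end state n_probes``
  (optional ``copy_number``), one call per row.
* Genetic maps — HapMap-style text: ``position  rate(cM/Mb)  cM`` per
  chromosome, or a four-column variant with a leading chromosome column.
* Phased haplotypes — VCF with phased GT fields (read through cyvcf2), or a
  simple tab-separated matrix dialect (see :func:`read_haplotype_matrix`).
* Phenotypes — TSV ``sample  aud  diagnoses`` where diagnoses is a
  comma-separated list of labels (may be empty).
* Gene intervals — BED (0-based half-open on disk, converted on read).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STATES = ("DEL", "DUP")

#: Autosome labels accepted with or without a "chr" prefix.
AUTOSOMES = frozenset(str(i) for i in range(1, 23)) | frozenset(
    f"chr{i}" for i in range(1, 23)
)


class FormatError(ValueError):
    """A file does not conform to its expected layout (missing columns, ...)."""


class RecordError(ValueError):
    """One or more records violate a field invariant; the message names rows."""


class MapLookupError(KeyError):
    """A chromosome queried against a genetic map that does not cover it."""


def is_autosome(chrom: str) -> bool:
    return chrom in AUTOSOMES


# ---------------------------------------------------------------------------
# CNV calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CNVCall:
    """A single caller's interval call for one sample (1-based inclusive)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    state: str
    n_probes: int
    caller: str = ""
    copy_number: int | None = None

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise RecordError(f"state must be one of {VALID_STATES}, got {self.state!r}")
        if self.end_bp < self.start_bp:
            raise RecordError(
                f"end_bp < start_bp ({self.end_bp} < {self.start_bp}) for "
                f"{self.sample_id} {self.chrom}"
            )
        if self.n_probes < 0:
            raise RecordError("n_probes must be non-negative")
        if self.copy_number is not None:
            cn = self.copy_number
            if not 0 <= cn <= 4:
                raise RecordError(f"copy_number out of range 0-4: {cn}")
            if (self.state == "DEL") != (cn < 2) and (self.state == "DUP") != (cn > 2):
                raise RecordError(
                    f"state {self.state} inconsistent with copy_number {cn}"
                )

    @property
    def size_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


_CNV_COLUMNS = ["sample", "chrom", "start", "end", "state", "n_probes"]


def read_cnv_calls(path: str | Path, caller: str) -> list[CNVCall]:
    """Read a CNV call TSV, labelling every call with ``caller``.

    Rows violating field invariants are rejected collectively with a
    :class:`RecordError` naming the offending 1-based data rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in _CNV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    calls: list[CNVCall] = []
    bad: list[str] = []
    has_cn = "copy_number" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cn = getattr(row, "copy_number", None) if has_cn else None
        if cn is not None and pd.isna(cn):
            cn = None
        try:
            calls.append(
                CNVCall(
                    sample_id=str(row.sample),
                    chrom=str(row.chrom),
                    start_bp=int(row.start),
                    end_bp=int(row.end),
                    state=str(row.state),
                    n_probes=int(row.n_probes),
                    caller=caller,
                    copy_number=int(cn) if cn is not None else None,
                )
            )
        except (RecordError, ValueError) as exc:
            bad.append(f"row {i}: {exc}")
    if bad:
        raise RecordError(f"{path}: rejected {len(bad)} row(s): " + "; ".join(bad))
    return calls


def write_cnv_calls(calls: Iterable[CNVCall], path: str | Path) -> None:
    rows = [
        {
            "sample": c.sample_id,
            "chrom": c.chrom,
            "start": c.start_bp,
            "end": c.end_bp,
            "state": c.state,
            "n_probes": c.n_probes,
            "copy_number": c.copy_number if c.copy_number is not None else "",
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CNV_COLUMNS + ["copy_number"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Piecewise-linear genetic map: per-chromosome anchors of
    (position_bp, rate cM/Mb, cumulative cM).

    Between anchors, cumulative cM is linearly interpolated; beyond the map
    ends it is extrapolated with the terminal anchor's local rate.
    """

    chromosomes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def add_chromosome(
        self,
        chrom: str,
        positions_bp: Sequence[int],
        rates_cm_per_mb: Sequence[float],
        cumulative_cm: Sequence[float],
    ) -> None:
        pos = np.asarray(positions_bp, dtype=float)
        rate = np.asarray(rates_cm_per_mb, dtype=float)
        cum = np.asarray(cumulative_cm, dtype=float)
        if not (len(pos) == len(rate) == len(cum)) or len(pos) == 0:
            raise FormatError(f"{chrom}: anchor arrays empty or of unequal length")
        if np.any(np.diff(pos) <= 0):
            raise FormatError(f"{chrom}: anchor positions not strictly increasing")
        if np.any(np.diff(cum) < 0):
            raise FormatError(f"{chrom}: cumulative cM decreases")
        if np.any(rate < 0):
            raise FormatError(f"{chrom}: negative recombination rate")
        self.chromosomes[chrom] = (pos, rate, cum)

    def cm_at(self, chrom: str, pos_bp) -> np.ndarray | float:
        """Cumulative genetic position (cM) at ``pos_bp`` (scalar or array)."""
        if chrom not in self.chromosomes:
            raise MapLookupError(f"chromosome {chrom!r} not in genetic map")
        pos, rate, cum = self.chromosomes[chrom]
        q = np.asarray(pos_bp, dtype=float)
        out = np.interp(q, pos, cum)
        below = q < pos[0]
        above = q > pos[-1]
        if np.any(below):
            out = np.where(below, cum[0] - (pos[0] - q) * rate[0] * 1e-6, out)
        if np.any(above):
            out = np.where(above, cum[-1] + (q - pos[-1]) * rate[-1] * 1e-6, out)
        return float(out) if np.isscalar(pos_bp) or np.ndim(pos_bp) == 0 else out

    def morgans_at(self, chrom: str, pos_bp) -> np.ndarray | float:
        res = self.cm_at(chrom, pos_bp)
        return res / 100.0

    def morgans_between(self, chrom: str, a_bp, b_bp) -> np.ndarray | float:
        """Genetic distance in Morgans from a_bp to b_bp (signed)."""
        return (self.cm_at(chrom, b_bp) - self.cm_at(chrom, a_bp)) / 100.0


def uniform_map(chrom: str, start_bp: int, end_bp: int, rate_cm_per_mb: float) -> GeneticMap:
    """Constant-rate map over [start_bp, end_bp] — two anchors suffice."""
    gmap = GeneticMap()
    span_cm = (end_bp - start_bp) * rate_cm_per_mb * 1e-6
    gmap.add_chromosome(chrom, [start_bp, end_bp], [rate_cm_per_mb] * 2, [0.0, span_cm])
    return gmap


def read_genetic_map(path: str | Path, chrom: str | None = None) -> GeneticMap:
    """Read a HapMap-style genetic map.

    Three whitespace/tab-separated columns (position, rate cM/Mb, cumulative
    cM) require ``chrom``; a four-column file carries the chromosome in
    column one. A non-numeric first line is treated as a header.
    """
    rows: list[tuple[str, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                if len(parts) >= 4:
                    rows.append((parts[0], float(parts[1]), float(parts[2]), float(parts[3])))
                elif len(parts) == 3:
                    if chrom is None:
                        raise FormatError(
                            f"{path}: 3-column map needs an explicit chrom argument"
                        )
                    rows.append((chrom, float(parts[0]), float(parts[1]), float(parts[2])))
                else:
                    raise FormatError(f"{path}:{lineno}: expected 3 or 4 columns")
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric map entry")
    if not rows:
        raise FormatError(f"{path}: empty genetic map")
    gmap = GeneticMap()
    df = pd.DataFrame(rows, columns=["chrom", "pos", "rate", "cm"])
    for c, sub in df.groupby("chrom", sort=False):
        gmap.add_chromosome(c, sub["pos"].values, sub["rate"].values, sub["cm"].values)
    return gmap


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\trate_cM_Mb\tcM\n")
        for chrom, (pos, rate, cum) in gmap.chromosomes.items():
            for p, r, c in zip(pos, rate, cum):
                fh.write(f"{chrom}\t{int(p)}\t{r:.10g}\t{c:.10g}\n")


# ---------------------------------------------------------------------------
# Haplotype panel
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes over ordered SNP positions.

    ``alleles`` is (n_haplotypes, n_snps) with 0/1 codes; haplotype ids are
    ``<sample>_h1`` / ``<sample>_h2`` for diploid samples.
    """

    chrom: str
    positions: np.ndarray
    alleles: np.ndarray
    hap_ids: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.hap_ids), len(self.positions)):
            raise FormatError("allele matrix shape does not match ids × positions")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise FormatError("SNP positions not strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return len(self.hap_ids)

    @property
    def n_snps(self) -> int:
        return len(self.positions)

    def haplotype(self, hap_id: str) -> np.ndarray:
        return self.alleles[self.hap_ids.index(hap_id)]

    @staticmethod
    def sample_of(hap_id: str) -> str:
        """Sample id from a haplotype id (strip a trailing _h<k> phase index)."""
        base, sep, tail = hap_id.rpartition("_h")
        return base if sep and tail.isdigit() else hap_id

    def subset(self, hap_ids: Sequence[str]) -> "HaplotypePanel":
        idx = [self.hap_ids.index(h) for h in hap_ids]
        return HaplotypePanel(
            self.chrom, self.positions.copy(), self.alleles[idx], list(hap_ids)
        )


class UnphasedGenotypeError(RecordError):
    """A heterozygous genotype without phase information ("0/1")."""


def read_haplotypes_vcf(
    path: str | Path, on_missing: str = "drop-site"
) -> HaplotypePanel:
    """Read phased haplotypes from a VCF (plain or bgzipped).

    Multi-allelic sites are skipped with a logged count. A heterozygous
    unphased genotype raises :class:`UnphasedGenotypeError` naming the site;
    homozygous genotypes are accepted regardless of the phase separator.
    Sites with missing alleles are dropped (``on_missing="drop-site"``,
    logged) or raise (``on_missing="fail"``).
    """
    from cyvcf2 import VCF

    if on_missing not in ("drop-site", "fail"):
        raise ValueError("on_missing must be 'drop-site' or 'fail'")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    chrom: str | None = None
    n_multi = n_missing = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            raise FormatError(f"{path}: multiple chromosomes ({chrom}, {var.CHROM})")
        col = np.empty(2 * len(samples), dtype=np.int8)
        drop = False
        for si, gt in enumerate(var.genotypes):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if a0 < 0 or a1 < 0:
                if on_missing == "fail":
                    raise RecordError(
                        f"{path}: missing allele at {var.CHROM}:{var.POS} sample {samples[si]}"
                    )
                drop = True
                break
            if not phased and a0 != a1:
                raise UnphasedGenotypeError(
                    f"{path}: unphased heterozygote at {var.CHROM}:{var.POS} "
                    f"sample {samples[si]}"
                )
            col[2 * si] = a0
            col[2 * si + 1] = a1
        if drop:
            n_missing += 1
            continue
        positions.append(var.POS)
        columns.append(col)
    if n_multi:
        logger.info("read_haplotypes_vcf: skipped %d multi-allelic site(s)", n_multi)
    if n_missing:
        logger.info("read_haplotypes_vcf: dropped %d site(s) with missing alleles", n_missing)
    if not positions:
        raise FormatError(f"{path}: no usable biallelic phased sites")
    hap_ids = [f"{s}_h{k}" for s in samples for k in (1, 2)]
    alleles = np.stack(columns, axis=1)
    return HaplotypePanel(chrom or "", np.asarray(positions), alleles, hap_ids)


def write_haplotypes_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF (REF=A, ALT=G placeholders)."""
    samples = sorted(dict.fromkeys(HaplotypePanel.sample_of(h) for h in panel.hap_ids))
    idx = {h: i for i, h in enumerate(panel.hap_ids)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for j, pos in enumerate(panel.positions):
            gts = []
            for s in samples:
                a0 = panel.alleles[idx[f"{s}_h1"], j]
                a1 = panel.alleles[idx[f"{s}_h2"], j]
                gts.append(f"{a0}|{a1}")
            fh.write(
                f"{panel.chrom}\t{int(pos)}\t.\tA\tG\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_haplotype_matrix(path: str | Path) -> HaplotypePanel:
    """Read the simple matrix dialect:

    ``#chrom=<label>`` on line one, then a header row ``hap_id <pos> <pos>
    ...`` and one row of 0/1 alleles per haplotype.
    """
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#chrom="):
            raise FormatError(f"{path}: expected '#chrom=<label>' on line 1")
        chrom = first.split("=", 1)[1]
        header = fh.readline().split()
        if not header or header[0] != "hap_id":
            raise FormatError(f"{path}: expected 'hap_id' header row")
        positions = [int(p) for p in header[1:]]
        hap_ids: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            hap_ids.append(parts[0])
            rows.append([int(a) for a in parts[1:]])
    return HaplotypePanel(chrom, np.asarray(positions), np.asarray(rows, dtype=np.int8), hap_ids)


def write_haplotype_matrix(panel: HaplotypePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#chrom={panel.chrom}\n")
        fh.write("hap_id\t" + "\t".join(str(int(p)) for p in panel.positions) + "\n")
        for hid, row in zip(panel.hap_ids, panel.alleles):
            fh.write(hid + "\t" + "\t".join(str(int(a)) for a in row) + "\n")


def read_haplotypes(path: str | Path, **kwargs) -> HaplotypePanel:
    """Dispatch on extension: .vcf/.vcf.gz → VCF reader, else matrix dialect."""
    name = str(path)
    if name.endswith(".vcf") or name.endswith(".vcf.gz"):
        return read_haplotypes_vcf(path, **kwargs)
    return read_haplotype_matrix(path)


# ---------------------------------------------------------------------------
# Phenotypes and genes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeRecord:
    sample_id: str
    aud: int
    diagnoses: frozenset[str]

    @property
    def any_psych(self) -> int:
        return int(bool(self.diagnoses))


@dataclass
class PhenotypeTable:
    """Per-sample AUD status and psychiatric diagnosis labels.

    ``diagnoses`` always includes "AUD" when ``aud`` is 1, so the derived
    "any psychiatric diagnosis" indicator is the union of all labels
    including AUD.
    """

    records: dict[str, PhenotypeRecord]

    @classmethod
    def from_mappings(
        cls, aud: Mapping[str, int], diagnoses: Mapping[str, Iterable[str]] | None = None
    ) -> "PhenotypeTable":
        diagnoses = diagnoses or {}
        recs = {}
        for sid, a in aud.items():
            labels = set(diagnoses.get(sid, ()))
            if a:
                labels.add("AUD")
            recs[sid] = PhenotypeRecord(sid, int(a), frozenset(labels))
        return cls(recs)

    @property
    def samples(self) -> list[str]:
        return list(self.records)

    def aud_status(self) -> dict[str, int]:
        return {s: r.aud for s, r in self.records.items()}

    def any_psych_status(self) -> dict[str, int]:
        return {s: r.any_psych for s, r in self.records.items()}


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("sample", "aud"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    aud = {}
    diags = {}
    for row in df.itertuples(index=False):
        aud[row.sample] = int(row.aud)
        raw = getattr(row, "diagnoses", "")
        diags[row.sample] = {d for d in str(raw).split(",") if d}
    return PhenotypeTable.from_mappings(aud, diags)


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\taud\tdiagnoses\tany_psych\n")
        for r in table.records.values():
            fh.write(f"{r.sample_id}\t{r.aud}\t{','.join(sorted(r.diagnoses))}\t{r.any_psych}\n")


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    name: str


def read_genes_bed(path: str | Path) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open → 1-based inclusive)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: BED needs chrom,start,end,name")
            genes.append(
                GeneInterval(parts[0], int(parts[1]) + 1, int(parts[2]), parts[3])
            )
    return genes
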