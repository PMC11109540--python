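"""Streaming VCF reader/writer for diploid biallelic genotype manipulation.

Thin layer over :mod:`pysam` that exposes each record's per-sample genotype
calls pre-classified into the five states the error model is defined over
(hom-ref, het, hom-alt, missing, other), while carrying the underlying
``pysam.VariantRecord`` untouched so that everything we do not explicitly
mutate round-trips verbatim.

Coordinates are VCF-native (1-based); no internal conversion is performed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Tuple

import pysam

__all__ = [
    "GTClass",
    "GenotypeCall",
    "SiteRecord",
    "VcfError",
    "read_vcf",
    "write_vcf",
    "locate_sample",
    "open_writer",
]


class VcfError(RuntimeError):
    """Fatal problem reading, writing or interpreting a VCF."""


class GTClass(enum.Enum):
    """Genotype class of one diploid call at one biallelic site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"
    OTHER = "other"

    def __repr__(self) -> str:  # compact in test diffs
        return self.name


#: The three states the error model can act on.
DIPLOID_STATES = (GTClass.HOM_REF, GTClass.HET, GTClass.HOM_ALT)


def classify_alleles(alleles: Tuple[Optional[int], ...]) -> GTClass:
    """Classify a tuple of allele indices (``None`` = missing allele).

    The classification is total: {0,0} is hom-ref, {0,1} in either order is
    het, {1,1} is hom-alt, {None,None} is missing, and anything else —
    half-calls like ``./1``, allele indices above 1 (multiallelic genotypes),
    or ploidy other than 2 — is OTHER and passes through all downstream
    machinery untouched.
    """
    if len(alleles) != 2:
        return GTClass.OTHER
    a, b = alleles
    if a is None and b is None:
        return GTClass.MISSING
    if a is None or b is None:
        return GTClass.OTHER
    if a == 0 and b == 0:
        return GTClass.HOM_REF
    if a == 1 and b == 1:
        return GTClass.HOM_ALT
    if (a, b) in ((0, 1), (1, 0)):
        return GTClass.HET
    return GTClass.OTHER


@dataclass
class GenotypeCall:
    """One sample's call at one site.

    ``allele_a``/``allele_b`` are allele indices into ``[ref] + alts`` or
    ``None`` for a missing allele. ``klass`` is derived purely from the
    allele pair, never stored independently.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    phased: bool = False

    @property
    def alleles(self) -> Tuple[Optional[int], Optional[int]]:
        return (self.allele_a, self.allele_b)

    @property
    def klass(self) -> GTClass:
        return classify_alleles((self.allele_a, self.allele_b))

    @classmethod
    def from_pysam(cls, sample: "pysam.libcbcf.VariantRecordSample") -> "GenotypeCall":
        gt = sample.get("GT", (None,))
        if gt is None:
            gt = (None,)
        if len(gt) != 2:
            # non-diploid call: classify as OTHER via a sentinel allele pair
            padded = tuple(gt) + (None, None)
            return cls(padded[0] if gt else None, -1, bool(sample.phased))
        return cls(gt[0], gt[1], bool(sample.phased))

    def gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        fmt = lambda a: "." if a is None else str(a)
        return fmt(self.allele_a) + sep + fmt(self.allele_b)


@dataclass
class SiteRecord:
    """One VCF data line with per-sample calls and the raw pysam payload.

    ``raw`` carries ID, QUAL, FILTER, INFO and all non-GT FORMAT values;
    writing a SiteRecord emits ``raw``, so anything not explicitly rewritten
    through :meth:`set_call` round-trips semantically identical.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: Tuple[str, ...]
    calls: list = field(default_factory=list)
    raw: Optional[pysam.VariantRecord] = None

    @classmethod
    def from_pysam(cls, rec: pysam.VariantRecord) -> "SiteRecord":
        calls = [GenotypeCall.from_pysam(rec.samples[i]) for i in range(len(rec.samples))]
        return cls(
            chrom=rec.chrom,
            pos=rec.pos,
            ref_allele=rec.ref or "",
            alt_alleles=tuple(rec.alts or ()),
            calls=calls,
            raw=rec,
        )

    def set_call(self, sample_index: int, call: GenotypeCall) -> None:
        """Rewrite one sample's GT (and phase flag) in place.

        Only the GT subfield is touched; other FORMAT subfields of the
        sample pass through unchanged.
        """
        self.calls[sample_index] = call
        if self.raw is not None:
            self.raw.samples[sample_index]["GT"] = (call.allele_a, call.allele_b)
            self.raw.samples[sample_index].phased = call.phased


def read_vcf(path: str) -> Tuple[pysam.VariantHeader, Iterator[SiteRecord]]:
    """Open ``path`` (plain or bgzipped VCF) and stream its records.

    Returns the header and a lazy iterator of :class:`SiteRecord` in file
    order. Raises :class:`VcfError` naming the path if the file cannot be
    opened or a record cannot be parsed.
    """
    verbosity = pysam.set_verbosity(0)  # mute htslib's missing-index chatter
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfError(f"cannot read VCF {path!r}: {exc}") from exc
    finally:
        pysam.set_verbosity(verbosity)

    def _iter() -> Iterator[SiteRecord]:
        try:
            with vf:
                for rec in vf:
                    yield SiteRecord.from_pysam(rec)
        except (OSError, ValueError) as exc:
            raise VcfError(f"malformed record in {path!r}: {exc}") from exc

    return vf.header, _iter()


def open_writer(header: pysam.VariantHeader, path: str) -> pysam.VariantFile:
    """Open a VCF writer; bgzipped when ``path`` ends in ``.gz``, text
    otherwise, uncompressed text on ``-`` (standard output)."""
    mode = "wz" if str(path).endswith(".gz") else "w"
    try:
        return pysam.VariantFile(str(path), mode, header=header)
    except (OSError, ValueError) as exc:
        raise VcfError(f"cannot write VCF {path!r}: {exc}") from exc


def write_vcf(header: pysam.VariantHeader, records: Iterable[SiteRecord], path: str) -> str:
    """Write records to ``path``; returns the path written."""
    with open_writer(header, path) as out:
        for site in records:
            if site.raw is None:
                raise VcfError(f"record {site.chrom}:{site.pos} has no payload to write")
            out.write(site.raw)
    return str(path)


def locate_sample(header: pysam.VariantHeader, sample_id: str) -> int:
    """Column index of ``sample_id`` in the header.

    Raises :class:`VcfError` listing the available samples when absent, and
    rejects headers with duplicate sample names as ambiguous (the VCF spec
    requires sample identifiers to be unique).
    """
    samples = list(header.samples)
    hits = [i for i, s in enumerate(samples) if s == sample_id]
    if not hits:
        preview = ", ".join(samples[:8]) + (" ..." if len(samples) > 8 else "")
        raise VcfError(f"sample {sample_id!r} not found in header (available: {preview})")
    if len(hits) > 1 or len(set(samples)) != len(samples):
        raise VcfError(f"duplicate sample names in header make {sample_id!r} ambiguous")
    return hits[0]
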