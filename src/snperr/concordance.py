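"""Genotype concordance between a truth and a query VCF, and NRC.

For one sample present in both files, tally per-class matches and
mismatches keyed on the *truth* genotype class, build the full
truth-class × query-class transition matrix, and compute non-reference
concordance:

    NRC = 1 − (e_rr + e_ra + e_aa) / (e_rr + e_ra + e_aa + m_ra + m_aa)

where e_rr/e_ra/e_aa count mismatches at truth hom-ref/het/hom-alt sites
and m_ra/m_aa count matches at het/hom-alt sites. Hom-ref matches (m_rr)
are tallied but deliberately omitted from the score, so the abundant
trivially concordant hom-ref sites cannot inflate it.

Sites are matched across the two files by exact (chrom, pos, ref, alts);
both files must be sorted identically. By default a site where either call
is missing contributes to the matrix's missing row/column but not to the
e/m counts; ``missing_as_mismatch=True`` instead counts a query-missing
call at a truth-called site as a mismatch of the truth class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Set, Tuple

import numpy as np

from .vcf_io import DIPLOID_STATES, GTClass, VcfError, locate_sample, read_vcf

__all__ = ["ConcordanceTable", "ConcordanceError", "tally", "nrc"]

#: Row/column order of the transition matrix.
MATRIX_CLASSES = (GTClass.HOM_REF, GTClass.HET, GTClass.HOM_ALT, GTClass.MISSING)
_MIDX = {k: i for i, k in enumerate(MATRIX_CLASSES)}


class ConcordanceError(RuntimeError):
    """Fatal problem comparing the two VCFs."""


@dataclass
class ConcordanceTable:
    """Match/mismatch counts for one truth/query sample comparison."""

    e_rr: int = 0
    e_ra: int = 0
    e_aa: int = 0
    m_rr: int = 0
    m_ra: int = 0
    m_aa: int = 0
    #: truth class (row) × query class (column) over hom-ref/het/hom-alt/missing
    transition_matrix: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=np.int64))
    #: sites skipped: OTHER-class on either side, allele-mismatched records,
    #: and (under the default policy) sites with a missing call on either side
    excluded: int = 0

    @property
    def compared(self) -> int:
        return self.e_rr + self.e_ra + self.e_aa + self.m_rr + self.m_ra + self.m_aa

    def nrc(self) -> float:
        return nrc(self)

    def count(self, truth_klass: GTClass, query_klass: GTClass) -> int:
        return int(self.transition_matrix[_MIDX[truth_klass], _MIDX[query_klass]])

    def to_tsv(self) -> str:
        lines = []
        for name in ("e_rr", "e_ra", "e_aa", "m_rr", "m_ra", "m_aa"):
            lines.append(f"{name}\t{getattr(self, name)}")
        lines.append(f"excluded\t{self.excluded}")
        header = "truth\\query\t" + "\t".join(k.value for k in MATRIX_CLASSES)
        lines.append(header)
        for i, k in enumerate(MATRIX_CLASSES):
            row = "\t".join(str(int(v)) for v in self.transition_matrix[i])
            lines.append(f"{k.value}\t{row}")
        try:
            lines.append(f"NRC\t{self.nrc():.6f}")
        except ConcordanceError:
            lines.append("NRC\tNA")
        return "\n".join(lines) + "\n"


_E_FIELD = {GTClass.HOM_REF: "e_rr", GTClass.HET: "e_ra", GTClass.HOM_ALT: "e_aa"}
_M_FIELD = {GTClass.HOM_REF: "m_rr", GTClass.HET: "m_ra", GTClass.HOM_ALT: "m_aa"}

_SiteKey = Tuple[int, int, str, Tuple[str, ...]]


def _keyed_stream(
    path: str, sample_id: str, label: str
) -> Iterator[Tuple[_SiteKey, GTClass, str]]:
    """Yield (sortable site key, sample's genotype class, display position).

    Contigs are ranked by header order when declared, else by first
    appearance; a key decrease means the file is unsorted and is fatal.
    """
    header, records = read_vcf(path)
    idx = locate_sample(header, sample_id)
    contig_rank: Dict[str, int] = {name: i for i, name in enumerate(header.contigs)}
    last_key: Optional[Tuple[int, int]] = None
    for site in records:
        rank = contig_rank.setdefault(site.chrom, len(contig_rank))
        pos_key = (rank, site.pos)
        if last_key is not None and pos_key < last_key:
            raise ConcordanceError(
                f"{label} VCF {path!r} is not sorted at {site.chrom}:{site.pos}"
            )
        last_key = pos_key
        key = (rank, site.pos, site.ref_allele, site.alt_alleles)
        yield key, site.calls[idx].klass, f"{site.chrom}:{site.pos}"


def _load_site_keys(path: str) -> Set[Tuple[str, int, str, Tuple[str, ...]]]:
    _, records = read_vcf(path)
    return {(s.chrom, s.pos, s.ref_allele, s.alt_alleles) for s in records}


def tally(
    truth_vcf: str,
    query_vcf: str,
    sample_id: str,
    sites: Optional[str] = None,
    missing_as_mismatch: bool = False,
) -> ConcordanceTable:
    """Compare one sample between a truth and a query VCF.

    The comparison runs over the intersection of sites present in both
    files (matched by exact chrom/pos/ref/alts), further restricted to the
    sites in ``sites`` when given. Records sharing a position but differing
    in alleles are excluded and counted, as are OTHER-class calls on either
    side.
    """
    restrict = _load_site_keys(sites) if sites is not None else None

    table = ConcordanceTable()
    t_stream = _keyed_stream(truth_vcf, sample_id, "truth")
    q_stream = _keyed_stream(query_vcf, sample_id, "query")

    # merge-join: group each stream's consecutive records by (contig, pos)
    t_item = next(t_stream, None)
    q_item = next(q_stream, None)
    while t_item is not None and q_item is not None:
        t_pos, q_pos = t_item[0][:2], q_item[0][:2]
        if t_pos < q_pos:
            t_item = next(t_stream, None)
            continue
        if q_pos < t_pos:
            q_item = next(q_stream, None)
            continue
        # same position in both files: collect the co-located record groups
        t_group: List[Tuple[_SiteKey, GTClass, str]] = []
        while t_item is not None and t_item[0][:2] == t_pos:
            t_group.append(t_item)
            t_item = next(t_stream, None)
        q_group: List[Tuple[_SiteKey, GTClass, str]] = []
        while q_item is not None and q_item[0][:2] == q_pos:
            q_group.append(q_item)
            q_item = next(q_stream, None)
        q_by_alleles = {key[2:]: (key, klass, disp) for key, klass, disp in q_group}
        for key, t_klass, disp in t_group:
            match = q_by_alleles.pop(key[2:], None)
            if match is None:
                table.excluded += 1  # same position, different alleles
                continue
            _, q_klass, _ = match
            if restrict is not None:
                chrom = disp.rsplit(":", 1)[0]
                if (chrom, key[1], key[2], key[3]) not in restrict:
                    continue
            _score_site(table, t_klass, q_klass, missing_as_mismatch)
        table.excluded += len(q_by_alleles)
    return table


def _score_site(
    table: ConcordanceTable, t_klass: GTClass, q_klass: GTClass, missing_as_mismatch: bool
) -> None:
    if t_klass is GTClass.OTHER or q_klass is GTClass.OTHER:
        table.excluded += 1
        return
    table.transition_matrix[_MIDX[t_klass], _MIDX[q_klass]] += 1
    if t_klass is GTClass.MISSING:
        table.excluded += 1
        return
    if q_klass is GTClass.MISSING:
        if missing_as_mismatch:
            setattr(table, _E_FIELD[t_klass], getattr(table, _E_FIELD[t_klass]) + 1)
        else:
            table.excluded += 1
        return
    field_map = _M_FIELD if t_klass is q_klass else _E_FIELD
    setattr(table, field_map[t_klass], getattr(table, field_map[t_klass]) + 1)


def nrc(table: ConcordanceTable) -> float:
    """Non-reference concordance of a tallied table.

    Raises :class:`ConcordanceError` when the denominator is zero (no
    mismatches and no non-reference matches: the score is undefined because
    the comparison carries no non-reference information).
    """
    errors = table.e_rr + table.e_ra + table.e_aa
    denom = errors + table.m_ra + table.m_aa
    if denom == 0:
        raise ConcordanceError(
            "NRC undefined: no mismatches and no non-reference matches in the comparison"
        )
    return 1.0 - errors / denom
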