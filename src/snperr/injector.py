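"""Stochastic genotype-error injection into one sample of a multi-sample VCF.

The injector streams the input record by record; for the designated sample
it makes a single categorical draw per eligible genotype over that class's
transition distribution and, when an error mode is realized, rewrites the
GT subfield to the canonical unphased representative of the target class
(0/0, 0/1, 1/1 or ./.). Every other sample — and every other field of the
target sample — passes through byte-identical. Genotypes that are missing
or outside the diploid biallelic alphabet (half-calls, allele index > 1,
ploidy ≠ 2) are never touched.

A single seeded RNG stream drives the draws, one draw per eligible site in
file order, so (input, spec, seed) fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .error_model import (
    MODES,
    MODES_BY_SOURCE,
    ErrorSpec,
    transition_for,
    validate_spec,
)
from .vcf_io import DIPLOID_STATES, GenotypeCall, GTClass, locate_sample, open_writer, read_vcf

__all__ = ["InjectionReport", "mutate_call", "inject"]

#: Salt for the injector's RNG seed domain (see inject()).
_SEED_DOMAIN = 0x1D5E

#: Canonical unphased rewrite for each target class.
_CANONICAL: Dict[GTClass, Tuple[Optional[int], Optional[int]]] = {
    GTClass.HOM_REF: (0, 0),
    GTClass.HET: (0, 1),
    GTClass.HOM_ALT: (1, 1),
    GTClass.MISSING: (None, None),
}


@dataclass
class InjectionReport:
    """Exact tallies of one injection run.

    ``changes_by_mode`` counts realized transitions per mode; diffing input
    against output genotype classes reproduces it exactly, which is the
    closure the concordance evaluator verifies.
    """

    sample_id: str = ""
    seed: Optional[int] = None
    sites_scanned: int = 0
    eligible_by_class: Dict[GTClass, int] = field(
        default_factory=lambda: {k: 0 for k in DIPLOID_STATES}
    )
    changes_by_mode: Dict[str, int] = field(default_factory=lambda: {m: 0 for m in MODES})
    passthrough_other: int = 0

    @property
    def eligible_total(self) -> int:
        return sum(self.eligible_by_class.values())

    def to_tsv(self) -> str:
        lines = [f"sample\t{self.sample_id}", f"seed\t{self.seed}"]
        lines.append(f"sites_scanned\t{self.sites_scanned}")
        for klass in DIPLOID_STATES:
            lines.append(f"eligible_{klass.value}\t{self.eligible_by_class[klass]}")
        lines.append(f"passthrough_other\t{self.passthrough_other}")
        for mode in MODES:
            lines.append(f"changes_{mode}\t{self.changes_by_mode[mode]}")
        return "\n".join(lines) + "\n"


def mutate_call(
    call: GenotypeCall, spec: ErrorSpec, rng: np.random.Generator
) -> Tuple[GenotypeCall, Optional[str]]:
    """Apply one categorical draw to one genotype call.

    Returns ``(call, None)`` unchanged — without consuming randomness — for
    MISSING/OTHER calls. For eligible calls one uniform variate selects an
    outcome from the class's transition distribution; the stay outcome
    returns the call object untouched (phase and allele order preserved),
    any other outcome returns the canonical unphased representative of the
    target class together with the realized mode name.
    """
    klass = call.klass
    if klass not in MODES_BY_SOURCE:
        return call, None
    dist = transition_for(spec, klass)
    u = rng.random()
    acc = 0.0
    for target, mode, p in dist.outcomes[:-1]:
        acc += p
        if u < acc:
            if mode is None or target is klass:  # defensive; stay is last
                return call, None
            a, b = _CANONICAL[target]
            return GenotypeCall(a, b, phased=False), mode
    return call, None


def inject(
    input_vcf: str,
    sample_id: str,
    spec: ErrorSpec,
    seed: Optional[int] = None,
    output_vcf: str = "-",
) -> InjectionReport:
    """Stream ``input_vcf`` and rewrite the target sample's genotypes.

    Parameters
    ----------
    input_vcf:
        Path to a multi-sample VCF (plain or bgzipped).
    sample_id:
        The one sample whose genotypes are perturbed; must exist in the
        header.
    spec:
        Validated nine-mode probability specification.
    seed:
        Seed for the single RNG stream; ``None`` draws an entropy seed (the
        one actually used is recorded in the report).
    output_vcf:
        Destination path; ``-`` streams to standard output; a ``.gz``
        suffix selects bgzip compression.

    Returns the exact :class:`InjectionReport`. Sites appear in the output
    in input order; all non-target samples are genotype-identical to the
    input at every site.
    """
    validate_spec(spec)
    header, records = read_vcf(input_vcf)
    target = locate_sample(header, sample_id)

    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    # domain-salted stream: a user reusing one seed for cohort simulation
    # and injection must not replay the generator's uniforms here, or the
    # draws would correlate with the genotypes being mutated
    rng = np.random.default_rng(np.random.SeedSequence((_SEED_DOMAIN, seed)))

    report = InjectionReport(sample_id=sample_id, seed=seed)
    with open_writer(header, output_vcf) as out:
        for site in records:
            report.sites_scanned += 1
            call = site.calls[target]
            klass = call.klass
            if klass in report.eligible_by_class:
                report.eligible_by_class[klass] += 1
                new_call, mode = mutate_call(call, spec, rng)
                if mode is not None:
                    report.changes_by_mode[mode] += 1
                    site.set_call(target, new_call)
            else:
                report.passthrough_other += 1
            out.write(site.raw)
    return report
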