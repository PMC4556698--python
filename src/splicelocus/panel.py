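"""Phased genotype panels.

A :class:`PhasedPanel` holds the two haplotype alleles of every individual at
every variant and is the substrate for association, LD, haplotype and
simulation work.  Alleles are coded 0 (reference) / 1 (alternative); the two
haplotypes of an individual are ordered but the order carries no meaning
beyond phase consistency across variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ConfigError(ValueError):
    """Invalid simulation or analysis configuration."""


@dataclass(frozen=True)
class VariantDef:
    """A biallelic SNP with its population minor-allele frequency.

    ``maf`` is the frequency of ``alt_allele`` and must lie in (0, 0.5];
    positions are 1-based genomic coordinates.
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ConfigError(f"{self.id}: ref and alt alleles are identical")
        if not (0.0 < self.maf <= 0.5):
            raise ConfigError(f"{self.id}: maf {self.maf} outside (0, 0.5]")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ConfigError(f"{self.id}: only single-base alleles are supported")


@dataclass
class PhasedPanel:
    """individuals x variants x 2 phased haplotype alleles (0 = ref, 1 = alt)."""

    individuals: list[str]
    variants: list[VariantDef]
    alleles: np.ndarray = field(repr=False)  # shape (n, m, 2), int8

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        expected = (len(self.individuals), len(self.variants), 2)
        if self.alleles.shape != expected:
            raise ValueError(
                f"allele array shape {self.alleles.shape} != {expected}"
            )
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele values must be 0 or 1")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for i, v in enumerate(self.variants):
            if v.id == variant_id:
                return i
        raise KeyError(f"unknown variant id {variant_id!r}")

    def genotype(self, variant_id: str) -> np.ndarray:
        """Diploid alternative-allele counts (0/1/2) per individual."""
        return self.alleles[:, self.variant_index(variant_id), :].sum(axis=1)

    def haplotypes(self, variant_ids: list[str] | None = None) -> np.ndarray:
        """Allele matrix of shape (2 * n_individuals, m), chromosome-major.

        Row ``2*i`` and ``2*i + 1`` are the two haplotypes of individual ``i``.
        """
        if variant_ids is None:
            idx = np.arange(self.n_variants)
        else:
            idx = np.array([self.variant_index(v) for v in variant_ids])
        sub = self.alleles[:, idx, :]  # (n, k, 2)
        return sub.transpose(0, 2, 1).reshape(-1, len(idx))

    def allele_freq(self, variant_id: str) -> float:
        """Realized alternative-allele frequency."""
        if self.n_individuals == 0:
            raise ValueError("empty panel has no allele frequencies")
        return float(self.alleles[:, self.variant_index(variant_id), :].mean())
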