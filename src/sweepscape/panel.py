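"""Haplotype panels, allele-frequency tables and polarization.

The central container is :class:`HaplotypePanel`: a matrix of phased binary
haplotypes (rows = chromosomes, columns = segregating sites) over a genomic
region, carrying per-chromosome population labels and, when polarized, the
guarantee that ``0`` is the ancestral and ``1`` the derived allele at every
site whose ancestral state is known.  All sample sizes in this package are
chromosome counts; diploid individuals are always expanded to two rows.

Coordinates are 0-based half-open internally; VCF positions (1-based) are
converted on read and write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePanel",
    "FrequencyRecord",
    "read_panel",
    "read_hapmatrix",
    "write_hapmatrix",
    "write_vcf",
    "derived_allele_freq",
    "max_undetected_freq",
    "read_frequency_table",
]


class PanelError(ValueError):
    """Raised for malformed or inconsistent haplotype input."""


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes for one genomic region.

    Parameters
    ----------
    alleles
        ``(n_chromosomes, n_sites)`` array of 0/1 allele states.
    positions
        Region-local base-pair coordinates (0-based), strictly increasing.
    pop_labels
        Population identifier per chromosome.
    polarized
        If True, ``0`` means ancestral and ``1`` derived at every site where
        ``ancestral_known`` is True.
    ancestral_known
        Per-site flag; sites with unknown ancestral state are retained but
        must be masked by statistics that require polarization.
    region_length
        Length of the region in bp.
    """

    alleles: np.ndarray
    positions: np.ndarray
    pop_labels: np.ndarray
    polarized: bool = False
    ancestral_known: np.ndarray | None = None
    region_length: int | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.pop_labels = np.asarray(self.pop_labels)
        if self.alleles.ndim != 2:
            raise PanelError("alleles must be a 2-D matrix")
        n, s = self.alleles.shape
        if self.positions.shape != (s,):
            raise PanelError("positions length must equal the site count")
        if self.pop_labels.shape != (n,):
            raise PanelError("pop_labels length must equal the chromosome count")
        if s > 1 and not np.all(np.diff(self.positions) > 0):
            raise PanelError("positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise PanelError("allele states must be 0 or 1")
        counts = self.alleles.sum(axis=0)
        if np.any((counts == 0) | (counts == n)):
            raise PanelError("every site must be polymorphic in the pooled sample")
        if self.ancestral_known is None:
            self.ancestral_known = np.ones(s, dtype=bool)
        else:
            self.ancestral_known = np.asarray(self.ancestral_known, dtype=bool)
            if self.ancestral_known.shape != (s,):
                raise PanelError("ancestral_known length must equal the site count")
        if self.region_length is None:
            self.region_length = int(self.positions[-1]) + 1 if s else 0
        if s and self.positions[-1] >= self.region_length:
            raise PanelError("positions must lie inside [0, region_length)")

    # -- basic queries -------------------------------------------------

    @property
    def n_chromosomes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(str(p), None)
        return list(seen)

    def rows(self, population: str | None = None) -> np.ndarray:
        """Row indices belonging to ``population`` (all rows if None)."""
        if population is None:
            return np.arange(self.n_chromosomes)
        idx = np.flatnonzero(self.pop_labels.astype(str) == str(population))
        if idx.size == 0:
            raise PanelError(f"no chromosomes labelled {population!r}")
        return idx

    def derived_counts(self, population: str | None = None) -> np.ndarray:
        """Per-site count of 1-alleles within one population (or pooled)."""
        return self.alleles[self.rows(population)].sum(axis=0)

    def site_at(self, position: int) -> int:
        """Index of the site at base-pair ``position`` (exact match)."""
        i = int(np.searchsorted(self.positions, position))
        if i >= self.n_sites or self.positions[i] != position:
            raise PanelError(f"no site at position {position}")
        return i

    def take_sites(self, index: np.ndarray) -> "HaplotypePanel":
        """Sub-panel restricted to the given site indices (pooled-polymorphic)."""
        index = np.asarray(index)
        return HaplotypePanel(
            alleles=self.alleles[:, index],
            positions=self.positions[index],
            pop_labels=self.pop_labels,
            polarized=self.polarized,
            ancestral_known=self.ancestral_known[index],
            region_length=self.region_length,
        )


@dataclass
class FrequencyRecord:
    """Derived-allele frequency of one SNP in one population."""

    snp_id: str
    pop: str
    daf: float
    n_chrom: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.daf <= 1.0:
            raise PanelError(
                f"{self.snp_id}/{self.pop}: frequency {self.daf} outside [0, 1]"
            )
        if self.n_chrom <= 0:
            raise PanelError(f"{self.snp_id}/{self.pop}: non-positive sample size")


# ---------------------------------------------------------------------------
# I/O


def read_panel(
    path: str | Path,
    pop_assignment: dict[str, str],
    ancestral_tag: str | None = None,
    region_length: int | None = None,
) -> HaplotypePanel:
    """Read a phased panel from VCF or the plain haplotype-matrix format.

    ``pop_assignment`` maps sample names to population identifiers.  For VCF
    input, if ``ancestral_tag`` names an INFO key (typically ``AA``) whose
    value matches REF or ALT, alleles at that site are recoded so that 0 is
    ancestral; sites where the tag is missing or unresolvable are kept but
    flagged as unknown-ancestral.  Multiallelic sites are skipped with a
    logged warning; unphased genotypes are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in {".vcf", ".gz", ".bcf"} or path.name.endswith(".vcf.gz"):
        return _read_vcf(path, pop_assignment, ancestral_tag, region_length)
    return read_hapmatrix(path, pop_assignment=pop_assignment, region_length=region_length)


def _read_vcf(
    path: Path,
    pop_assignment: dict[str, str],
    ancestral_tag: str | None,
    region_length: int | None,
) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = [s for s in vcf.samples if s in pop_assignment]
    if not samples:
        raise PanelError("no VCF sample matches the population assignment")
    vcf.set_samples(samples)
    samples = list(vcf.samples)

    columns: list[np.ndarray] = []
    positions: list[int] = []
    known: list[bool] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping multiallelic site at %s:%d", var.CHROM, var.POS
            )
            continue
        gts = var.genotypes  # [a, b, phased] per sample
        hap = np.empty(2 * len(samples), dtype=np.int8)
        for j, g in enumerate(gts):
            if len(g) < 3 or not g[2]:
                raise PanelError(
                    f"unphased genotype for sample {samples[j]} at "
                    f"{var.CHROM}:{var.POS}"
                )
            hap[2 * j] = g[0]
            hap[2 * j + 1] = g[1]
        aa_known = False
        if ancestral_tag is not None:
            aa = var.INFO.get(ancestral_tag)
            if aa is not None:
                aa = str(aa).upper()
                if aa == var.REF.upper():
                    aa_known = True
                elif aa == var.ALT[0].upper():
                    hap = (1 - hap).astype(np.int8)
                    aa_known = True
        c = hap.sum()
        if c == 0 or c == hap.size:
            n_skipped += 1
            logger.warning("skipping monomorphic site at %s:%d", var.CHROM, var.POS)
            continue
        columns.append(hap)
        positions.append(var.POS - 1)  # VCF is 1-based
        known.append(aa_known)
    if n_skipped:
        logger.info("skipped %d site(s)", n_skipped)
    labels = np.repeat([pop_assignment[s] for s in samples], 2)
    return HaplotypePanel(
        alleles=np.column_stack(columns) if columns else np.empty((2 * len(samples), 0), np.int8),
        positions=np.array(positions, dtype=np.int64),
        pop_labels=labels,
        polarized=ancestral_tag is not None,
        ancestral_known=np.array(known, dtype=bool) if ancestral_tag else None,
        region_length=region_length,
    )


def read_hapmatrix(
    path: str | Path,
    pop_assignment: dict[str, str] | None = None,
    region_length: int | None = None,
) -> HaplotypePanel:
    """Read the plain-text haplotype matrix format.

    First line: whitespace-separated site positions (0-based bp).  Each
    following line: a chromosome as a string of 0/1 characters.  A sidecar
    file ``<path>.pops`` with one population label per line supplies the
    labels; alternatively ``pop_assignment`` maps row index (as text) to a
    label.
    """
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    positions = np.array(lines[0].split(), dtype=np.int64)
    rows = [np.frombuffer(ln.strip().encode(), dtype=np.uint8) - ord("0") for ln in lines[1:]]
    alleles = np.array(rows, dtype=np.int8)
    side = path.with_suffix(path.suffix + ".pops")
    if side.exists():
        labels = np.array(side.read_text().split())
    elif pop_assignment is not None:
        labels = np.array([pop_assignment[str(i)] for i in range(len(rows))])
    else:
        labels = np.array(["pop0"] * len(rows))
    meta = path.with_suffix(path.suffix + ".meta")
    if region_length is None and meta.exists():
        region_length = int(meta.read_text().split()[0])
    return HaplotypePanel(
        alleles=alleles,
        positions=positions,
        pop_labels=labels,
        polarized=True,
        region_length=region_length,
    )


def write_hapmatrix(panel: HaplotypePanel, path: str | Path) -> None:
    """Write the plain-text haplotype matrix plus sidecar label/meta files."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(" ".join(str(int(p)) for p in panel.positions) + "\n")
        for row in panel.alleles:
            fh.write("".join("1" if a else "0" for a in row) + "\n")
    path.with_suffix(path.suffix + ".pops").write_text(
        "\n".join(str(p) for p in panel.pop_labels) + "\n"
    )
    path.with_suffix(path.suffix + ".meta").write_text(f"{panel.region_length}\n")


def write_vcf(panel: HaplotypePanel, path: str | Path, chrom: str = "1") -> None:
    """Write the panel as an uncompressed phased VCF (0 = REF = ancestral)."""
    if panel.n_chromosomes % 2:
        raise PanelError("VCF output requires an even chromosome count")
    n_ind = panel.n_chromosomes // 2
    names = [f"{panel.pop_labels[2 * i]}_{i}" for i in range(n_ind)]
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={panel.region_length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(names)
            + "\n"
        )
        for j in range(panel.n_sites):
            info = "AA=A" if (panel.polarized and panel.ancestral_known[j]) else "."
            gts = "\t".join(
                f"{panel.alleles[2 * i, j]}|{panel.alleles[2 * i + 1, j]}"
                for i in range(n_ind)
            )
            fh.write(
                f"{chrom}\t{panel.positions[j] + 1}\t.\tA\tT\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Frequencies


def derived_allele_freq(
    panel: HaplotypePanel, site_index: int, population: str | None = None
) -> float:
    """Derived-allele frequency at one site within one population.

    Requires the site to be polarized (ancestral state known); the frequency
    is the count of 1-alleles divided by the population's chromosome count.
    """
    if not (panel.polarized and panel.ancestral_known[site_index]):
        raise PanelError(
            f"site {site_index} is not polarized; polarize the panel first"
        )
    rows = panel.rows(population)
    return float(panel.alleles[rows, site_index].sum()) / rows.size


def max_undetected_freq(m: int, alpha: float) -> float:
    """Highest population frequency not excluded by observing 0 copies in m chromosomes.

    An allele at population frequency q is seen at least once among m sampled
    chromosomes with probability 1-(1-q)^m; the largest q that cannot be
    rejected at level ``alpha`` solves (1-q)^m = alpha, i.e.
    ``q = 1 - alpha**(1/m)``.  With m = 12 (six diploid individuals) and
    alpha = 0.05 this bound is 0.221.
    """
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValueError("m must be a positive integer chromosome count")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return 1.0 - alpha ** (1.0 / m)


def read_frequency_table(path: str | Path) -> list[FrequencyRecord]:
    """Read a TSV with columns snp_id, pop, daf, n_chrom.

    Malformed rows raise :class:`PanelError` naming the offending line.
    """
    path = Path(path)
    records: list[FrequencyRecord] = []
    with path.open() as fh:
        header = fh.readline().strip().split("\t")
        required = ["snp_id", "pop", "daf", "n_chrom"]
        if [h.strip() for h in header[: len(required)]] != required:
            raise PanelError(f"{path}: expected header {required}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                rec = FrequencyRecord(
                    snp_id=parts[0],
                    pop=parts[1],
                    daf=float(parts[2]),
                    n_chrom=int(parts[3]),
                )
            except (IndexError, ValueError, PanelError) as exc:
                raise PanelError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records
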