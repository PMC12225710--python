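"""Site frequency spectrum container, file I/O, folding and polarization.

The SFS for ``n = 2m`` haploid samples records how many sites carry the
derived allele in exactly ``i`` of the ``n`` chromosomes.  Index convention
throughout the package: ``i`` is the number of derived copies.  Polymorphic
classes are ``i = 1..n-1`` unfolded, ``i = 1..n//2`` folded; ``xi0`` is the
monomorphic (invariant) count and ``xi_n`` the all-derived class, which is
stored but never modeled (a second mutation would be required under the
infinite-sites assumption).

File dialects accepted by :func:`read_sfs`:

* full vector (dadi-style): header ``n=<n> unfolded`` then ``n+1`` counts
  ``xi0 xi1 .. xin`` (folded: ``n//2 + 1`` counts, ``xi0`` first);
* polymorphic-only (StairwayPlot-style): header additionally carries
  ``L=<total sites>`` and the count line holds only the polymorphic classes;
  the monomorphic count is recovered as ``L - sum(counts)``.  Without ``L``
  the monomorphic count is unknown and the monomorphic class is masked.

Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SiteFrequencySpectrum",
    "SFSFormatError",
    "read_sfs",
    "write_sfs",
    "fold_spectrum",
    "mask_spectrum",
    "apply_polarization_error",
]

logger = logging.getLogger(__name__)

MONOMORPHIC = "monomorphic"
SINGLETONS = "singletons"


class SFSFormatError(ValueError):
    """Raised when an SFS file does not parse or validate."""


@dataclass(frozen=True)
class SiteFrequencySpectrum:
    """An observed site frequency spectrum.

    Parameters
    ----------
    n
        Haploid sample size (``n = 2m`` for ``m`` diploids).
    counts
        SNP counts per polymorphic class.  Unfolded: length ``n - 1``,
        entry ``j`` is the count of sites with ``j + 1`` derived copies.
        Folded: length ``n // 2``, entry ``j`` is the count of sites with
        minor-allele count ``j + 1``.
    monomorphic_count
        Number of invariant sites (``xi0``), or ``None`` when unknown; in
        that case the monomorphic class must be masked.
    folded
        Whether derived/ancestral orientation has been collapsed.
    masked_classes
        Subset of ``{"monomorphic", "singletons"}`` excluded from the
        likelihood.
    xi_n
        Count of the all-derived class (unfolded only).  Recorded, never
        modeled.
    """

    n: int
    counts: tuple[int, ...]
    monomorphic_count: int | None = None
    folded: bool = False
    masked_classes: frozenset[str] = field(default_factory=frozenset)
    xi_n: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2 haploid samples, got n={self.n}")
        expected = self.n // 2 if self.folded else self.n - 1
        if len(self.counts) != expected:
            raise ValueError(
                f"counts length {len(self.counts)} does not match n={self.n} "
                f"({'folded' if self.folded else 'unfolded'}: expected {expected})"
            )
        counts = tuple(int(c) for c in self.counts)
        if any(c != float(o) for c, o in zip(counts, self.counts)) or any(
            c < 0 for c in counts
        ):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "masked_classes", frozenset(self.masked_classes))
        unknown = self.masked_classes - {MONOMORPHIC, SINGLETONS}
        if unknown:
            raise ValueError(f"unknown masked classes: {sorted(unknown)}")
        if self.monomorphic_count is None and MONOMORPHIC not in self.masked_classes:
            raise ValueError(
                "monomorphic count unknown: the monomorphic class must be masked"
            )
        if self.monomorphic_count is not None and self.monomorphic_count < 0:
            raise ValueError("monomorphic_count must be non-negative")
        if self.xi_n and self.folded:
            raise ValueError("a folded spectrum has no separate all-derived class")
        if self.xi_n > 0:
            logger.warning(
                "all-derived class xi_n=%d > 0; it is excluded from the likelihood",
                self.xi_n,
            )

    @property
    def m(self) -> int:
        """Number of diploid individuals."""
        return self.n // 2

    @property
    def segregating_sites(self) -> int:
        return int(sum(self.counts))

    @property
    def total_sites(self) -> int | None:
        """``l = xi0 + sum(counts)`` (+ ``xi_n``), or ``None`` when unknown."""
        if self.monomorphic_count is None:
            return None
        return self.monomorphic_count + self.segregating_sites + self.xi_n


def read_sfs(path: str | Path) -> SiteFrequencySpectrum:
    """Parse a plain-text SFS file (see module docstring for dialects)."""
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if len(lines) < 2:
        raise SFSFormatError(f"{path}: need a header line and a count line")
    header, count_line = lines[0], lines[1]

    n = None
    folded = None
    total = None
    for tok in header.replace(";", " ").split():
        low = tok.lower()
        if low.startswith("n="):
            n = int(tok[2:])
        elif low.startswith("l="):
            total = int(tok[2:])
        elif low in ("folded", "unfolded"):
            folded = low == "folded"
    if n is None or folded is None:
        raise SFSFormatError(
            f"{path}: header must declare n=<int> and folded/unfolded, got {header!r}"
        )

    try:
        values = [int(v) for v in count_line.split()]
    except ValueError as exc:
        raise SFSFormatError(f"{path}: non-integer count entry: {exc}") from exc
    if any(v < 0 for v in values):
        raise SFSFormatError(f"{path}: negative count entries are not allowed")

    n_poly = n // 2 if folded else n - 1
    n_full = n // 2 + 1 if folded else n + 1
    if len(values) == n_full and total is None:
        # full vector, xi0 first; unfolded ends with xi_n
        xi0 = values[0]
        if folded:
            counts, xi_n = values[1:], 0
        else:
            counts, xi_n = values[1:-1], values[-1]
        return SiteFrequencySpectrum(
            n=n, counts=tuple(counts), monomorphic_count=xi0, folded=folded, xi_n=xi_n
        )
    if len(values) == n_poly:
        if total is not None:
            xi0 = total - sum(values)
            if xi0 < 0:
                raise SFSFormatError(
                    f"{path}: declared total L={total} is smaller than the SNP sum"
                )
            return SiteFrequencySpectrum(
                n=n, counts=tuple(values), monomorphic_count=xi0, folded=folded
            )
        return SiteFrequencySpectrum(
            n=n,
            counts=tuple(values),
            monomorphic_count=None,
            folded=folded,
            masked_classes=frozenset({MONOMORPHIC}),
        )
    raise SFSFormatError(
        f"{path}: expected {n_poly} or {n_full} entries for n={n} "
        f"({'folded' if folded else 'unfolded'}), found {len(values)}"
    )


def write_sfs(sfs: SiteFrequencySpectrum, path: str | Path, comment: str = "") -> None:
    """Write a spectrum in the dialect that preserves all of its information."""
    path = Path(path)
    lines = []
    if comment:
        for ln in comment.splitlines():
            lines.append(f"# {ln}")
    orient = "folded" if sfs.folded else "unfolded"
    if sfs.monomorphic_count is None:
        lines.append(f"n={sfs.n} {orient}")
        lines.append(" ".join(str(c) for c in sfs.counts))
    else:
        lines.append(f"n={sfs.n} {orient}")
        full = [sfs.monomorphic_count, *sfs.counts]
        if not sfs.folded:
            full.append(sfs.xi_n)
        lines.append(" ".join(str(c) for c in full))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def fold_spectrum(sfs: SiteFrequencySpectrum) -> SiteFrequencySpectrum:
    """Collapse derived/ancestral orientation: class ``i`` merges with ``n-i``.

    The middle class (``i = n/2``, even ``n``) is kept as is; the all-derived
    class merges into the monomorphic count (no segregating variation).
    """
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n = sfs.n
    xi = np.asarray(sfs.counts)
    half = n // 2
    folded = [int(xi[i - 1] + xi[n - i - 1]) for i in range(1, half + (n % 2))]
    if n % 2 == 0:
        folded.append(int(xi[half - 1]))
    mono = None if sfs.monomorphic_count is None else sfs.monomorphic_count + sfs.xi_n
    return SiteFrequencySpectrum(
        n=n,
        counts=tuple(folded),
        monomorphic_count=mono,
        folded=True,
        masked_classes=sfs.masked_classes,
    )


def mask_spectrum(
    sfs: SiteFrequencySpectrum, classes: set[str]
) -> SiteFrequencySpectrum:
    """Return a copy with the given classes marked as excluded.

    Masking singletons zeroes the affected counts (class 1 and, unfolded,
    class ``n-1``); masking monomorphic drops the invariant-site count.
    """
    classes = frozenset(classes) | sfs.masked_classes
    counts = list(sfs.counts)
    mono = sfs.monomorphic_count
    if MONOMORPHIC in classes:
        mono = None
    if SINGLETONS in classes:
        counts[0] = 0
        if not sfs.folded:
            counts[-1] = 0
        if MONOMORPHIC not in classes:
            warnings.warn(
                "masking singletons without monomorphic: the likelihood will "
                "condition on classes 2..n-2 only",
                stacklevel=2,
            )
            classes = classes | {MONOMORPHIC}
            mono = None
    return replace(
        sfs, counts=tuple(counts), monomorphic_count=mono, masked_classes=classes
    )


def apply_polarization_error(
    sfs: SiteFrequencySpectrum, rho: float, seed: int | np.random.Generator
) -> SiteFrequencySpectrum:
    """Mis-polarize each SNP independently with probability ``rho``.

    A site with ``i`` derived copies whose ancestral allele is mis-called
    appears to have ``n - i`` derived copies.  Per class the number of moved
    sites is Binomial(count, rho); the total SNP count is conserved and the
    middle class (even ``n``) maps to itself.
    """
    if sfs.folded:
        raise ValueError("polarization error is undefined for a folded spectrum")
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rho must be a probability, got {rho}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = sfs.n
    xi = np.asarray(sfs.counts, dtype=np.int64)
    moved = rng.binomial(xi, rho)
    new = xi - moved + moved[::-1]  # class i receives movers from class n-i
    return replace(sfs, counts=tuple(int(c) for c in new))
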