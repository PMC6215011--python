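"""Genotype matrices, GENEPOP I/O, locus filtering and per-locus summaries.

The central container is :class:`GenotypeMatrix`: a diploid, biallelic
individuals × loci matrix coded as alternate-allele counts (0/1/2) with a
distinct missing sentinel, plus individual/locus identifiers and a
per-individual group label (here, wing morphotype).

Locus identifiers follow the ``tag_position`` convention of
reduced-representation (GBS/RAD) catalogues, e.g. ``"14459_12"`` — the
sequenced tag number and the SNP's offset within the tag.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1
"""Sentinel for a missing genotype call (never 0, which is a valid homozygote)."""


class GenepopFormatError(ValueError):
    """Raised when a GENEPOP stream violates the expected dialect."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic SNP calls for a set of individuals.

    Parameters
    ----------
    individual_ids
        Unique identifiers, one per row of ``calls``.
    locus_ids
        Unique identifiers, one per column, of the form ``tag_position``.
    calls
        ``(n_individuals, n_loci)`` integer array with entries in
        ``{0, 1, 2}`` (copies of the alternate allele) or :data:`MISSING`.
    group_labels
        Per-individual categorical label (e.g. morphotype).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.individual_ids = list(map(str, self.individual_ids))
        self.locus_ids = list(map(str, self.locus_ids))
        self.group_labels = list(map(str, self.group_labels))
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = self.calls.shape if self.calls.ndim == 2 else (-1, -1)
        if n != len(self.individual_ids) or m != len(self.locus_ids):
            raise ValueError(
                "calls shape %r inconsistent with %d individuals / %d loci"
                % (self.calls.shape, len(self.individual_ids), len(self.locus_ids))
            )
        if len(self.group_labels) != n:
            raise ValueError("one group label per individual required")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus_ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not ok.all():
            raise ValueError("calls must be 0/1/2 or the missing sentinel")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def group_levels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(g)
        return list(seen)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.individual_ids),
            list(self.locus_ids),
            self.calls.copy(),
            list(self.group_labels),
        )

    # -- subsetting --------------------------------------------------------
    def subset_individuals(
        self, ids: Sequence[str], labels: Sequence[str] | None = None
    ) -> "GenotypeMatrix":
        """Row-subset by identifier, optionally overriding group labels."""
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            rows = [index[i] for i in ids]
        except KeyError as exc:
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None
        new_labels = (
            list(labels) if labels is not None else [self.group_labels[r] for r in rows]
        )
        return GenotypeMatrix(
            [self.individual_ids[r] for r in rows],
            list(self.locus_ids),
            self.calls[rows, :],
            new_labels,
        )

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeMatrix":
        index = {lid: j for j, lid in enumerate(self.locus_ids)}
        cols = [index[l] for l in loci]
        return GenotypeMatrix(
            list(self.individual_ids),
            [self.locus_ids[c] for c in cols],
            self.calls[:, cols],
            list(self.group_labels),
        )

    # -- allele bookkeeping ------------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    def allele_counts(
        self, groups: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Alternate-allele counts and called gene copies per locus per group.

        Returns ``(a, n, levels)`` with ``a[i, j]`` the alternate-allele count
        at locus *i* in group *j* and ``n[i, j]`` the number of called gene
        copies (2 × non-missing individuals).
        """
        levels = list(groups) if groups is not None else self.group_levels
        labels = np.asarray(self.group_labels)
        a = np.zeros((self.n_loci, len(levels)), dtype=np.int64)
        n = np.zeros_like(a)
        called = self.called_mask()
        calls = np.where(called, self.calls, 0)
        for j, lev in enumerate(levels):
            rows = labels == lev
            a[:, j] = calls[rows].sum(axis=0)
            n[:, j] = 2 * called[rows].sum(axis=0)
        return a, n, levels

    def alt_freq(self) -> np.ndarray:
        """Pooled alternate-allele frequency per locus (called copies only)."""
        called = self.called_mask()
        copies = 2 * called.sum(axis=0)
        alt = np.where(called, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(copies > 0, alt / np.maximum(copies, 1), np.nan)


# ---------------------------------------------------------------------------
# GENEPOP I/O
# ---------------------------------------------------------------------------

_GENO_RE = re.compile(r"^\d{4}$|^\d{6}$")


def _split_genepop_row(line: str) -> tuple[str, list[str]]:
    if "," not in line:
        raise GenepopFormatError(f"sample row without comma separator: {line!r}")
    name, _, rest = line.partition(",")
    return name.strip(), rest.split()


def read_genepop(
    source: str | Path | io.TextIOBase,
    group_labels: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Parse a GENEPOP text stream into a :class:`GenotypeMatrix`.

    Accepts 2- or 3-digit allele codes; the all-zero code is a missing
    genotype.  Per locus, the two observed non-zero allele codes are mapped to
    reference (smaller code) and alternate (larger code); genotypes are
    recoded to alternate-allele counts.  POP blocks become group labels
    ``pop1, pop2, ...`` unless ``group_labels`` (one per individual, in file
    order) is supplied.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_genepop(fh, group_labels)

    lines = [ln.rstrip("\n") for ln in source]
    if not lines:
        raise GenepopFormatError("empty GENEPOP stream")
    # title line is free text and skipped
    body = lines[1:]

    locus_ids: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        chunk = body[i].strip()
        if chunk:
            locus_ids.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(body):
        raise GenepopFormatError("no POP delimiter found")

    individual_ids: list[str] = []
    pop_of_individual: list[int] = []
    rows: list[list[str]] = []
    pop = -1
    for ln in body[i:]:
        if not ln.strip():
            continue
        if ln.strip().lower() == "pop":
            pop += 1
            continue
        name, genos = _split_genepop_row(ln)
        if len(genos) != len(locus_ids):
            raise GenepopFormatError(
                f"row {name!r} has {len(genos)} genotypes, expected {len(locus_ids)}"
            )
        for g in genos:
            if not _GENO_RE.match(g):
                raise GenepopFormatError(f"malformed genotype {g!r} for {name!r}")
        individual_ids.append(name)
        pop_of_individual.append(pop)
        rows.append(genos)

    if not rows:
        raise GenepopFormatError("no sample rows found")

    n, m = len(rows), len(locus_ids)
    # decode allele pairs per locus
    calls = np.full((n, m), MISSING, dtype=np.int8)
    for j in range(m):
        width = len(rows[0][j]) // 2
        pairs = []
        for i_row in range(n):
            g = rows[i_row][j]
            if len(g) != 2 * width:
                raise GenepopFormatError(
                    f"mixed allele-code widths at locus {locus_ids[j]!r}"
                )
            pairs.append((int(g[:width]), int(g[width:])))
        alleles = sorted({a for p in pairs for a in p if a != 0})
        if len(alleles) > 2:
            raise GenepopFormatError(
                f"locus {locus_ids[j]!r} has more than two alleles: {alleles}"
            )
        if len(alleles) == 2:
            alt = alleles[-1]
        elif len(alleles) == 1 and alleles[0] > 1:
            # single observed code above the reference code: all-alternate locus
            alt = alleles[0]
        else:
            alt = None
        for i_row, (a1, a2) in enumerate(pairs):
            if a1 == 0 or a2 == 0:
                if a1 != a2:
                    raise GenepopFormatError(
                        f"half-missing genotype at locus {locus_ids[j]!r}"
                    )
                continue  # missing
            calls[i_row, j] = (alt is not None) * ((a1 == alt) + (a2 == alt))

    if group_labels is not None:
        if len(group_labels) != n:
            raise ValueError("group_labels length must match individual count")
        labels = list(group_labels)
    else:
        labels = [f"pop{p + 1}" for p in pop_of_individual]
    return GenotypeMatrix(individual_ids, locus_ids, calls, labels)


def write_genepop(
    gm: GenotypeMatrix,
    sink: str | Path | io.TextIOBase,
    title: str = "wingscan export",
) -> None:
    """Write the 3-digit GENEPOP dialect, one POP block per group label.

    Reference allele is coded ``001``, alternate ``002``, missing ``000000``.
    """
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise ValueError("refusing to write an empty GenotypeMatrix")
    if isinstance(sink, (str, Path)):
        with open(sink, "w") as fh:
            write_genepop(gm, fh, title)
        return

    code = {MISSING: "000000", 0: "001001", 1: "001002", 2: "002002"}
    sink.write(title + "\n")
    for lid in gm.locus_ids:
        sink.write(lid + "\n")
    for level in gm.group_levels:
        sink.write("POP\n")
        for i, iid in enumerate(gm.individual_ids):
            if gm.group_labels[i] != level:
                continue
            genos = " ".join(code[int(c)] for c in gm.calls[i])
            sink.write(f"{iid} , {genos}\n")


# ---------------------------------------------------------------------------
# Filtering and summaries
# ---------------------------------------------------------------------------


def _tag_and_position(locus_id: str) -> tuple[str, tuple[int, str]]:
    """Split ``tag_position``; position sorts numerically, then lexically."""
    tag, _, pos = locus_id.rpartition("_")
    if not tag:
        tag, pos = locus_id, ""
    try:
        return tag, (int(pos), pos)
    except ValueError:
        return tag, (np.iinfo(np.int64).max, pos)


def filter_loci(
    gm: GenotypeMatrix,
    min_call_rate: float = 0.5,
    min_maf: float = 0.05,
    one_per_tag: bool = True,
) -> GenotypeMatrix:
    """Apply the catalogue-level locus filters.

    Retains loci genotyped in at least ``min_call_rate`` of individuals and
    with pooled minor allele frequency at least ``min_maf`` (both thresholds
    inclusive), then optionally keeps a single SNP per tag (the lowest
    position, ties broken lexicographically).  Genotype values and individual
    order are never altered; the operation is idempotent.
    """
    for name, t in (("min_call_rate", min_call_rate), ("min_maf", min_maf)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")

    called = gm.called_mask()
    call_rate = called.sum(axis=0) / gm.n_individuals
    p = gm.alt_freq()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(p, 1.0 - p)
    keep = (call_rate >= min_call_rate) & np.nan_to_num(maf >= min_maf, nan=False)

    kept_ids = [lid for j, lid in enumerate(gm.locus_ids) if keep[j]]
    if one_per_tag:
        best: dict[str, tuple[tuple[int, str], str]] = {}
        for lid in kept_ids:
            tag, key = _tag_and_position(lid)
            if tag not in best or key < best[tag][0]:
                best[tag] = (key, lid)
        chosen = {lid for _, lid in best.values()}
        kept_ids = [lid for lid in kept_ids if lid in chosen]
    return gm.subset_loci(kept_ids)


def locus_summary(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus call rate, minor allele frequency and heterozygosities.

    Expected heterozygosity uses the small-sample correction
    ``2 p̂ (1 − p̂) · n_c / (n_c − 1)`` with ``n_c`` called gene copies, the
    convention of standard population-genetics software.
    """
    called = gm.called_mask()
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        bad = [gm.locus_ids[j] for j in np.where(n_called == 0)[0][:5]]
        raise ValueError(f"loci with zero called genotypes: {bad}")
    call_rate = n_called / gm.n_individuals
    p = gm.alt_freq()
    maf = np.minimum(p, 1.0 - p)
    ho = ((gm.calls == 1) & called).sum(axis=0) / n_called
    nc = 2.0 * n_called
    with np.errstate(invalid="ignore", divide="ignore"):
        he = np.where(nc > 1, 2.0 * p * (1.0 - p) * nc / (nc - 1.0), 0.0)
    return pd.DataFrame(
        {"call_rate": call_rate, "maf": maf, "ho": ho, "he": he},
        index=pd.Index(gm.locus_ids, name="locus_id"),
    )
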