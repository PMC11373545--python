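"""Domain types and file I/O for GWAS summary statistics, LD matrices and
protein-array expression matrices.

File dialect (all three formats): tab-separated, UTF-8, ``#``-prefixed comment
lines, ``NA`` as the missing token. Summary-statistics column names are
configurable through a ``column_map``; the defaults (SNP, CHR, POS, EA, OA,
EAF, BETA, SE, P, N) match common GWAS summary-stat exports. Positions are
1-based; alleles are uppercased on ingest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
MISSING = "NA"

#: default header names for summary-statistics files
DEFAULT_COLUMNS: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}


class FormatError(ValueError):
    """A file violates the expected layout or a field violates its range."""


class EmptyInputError(ValueError):
    """No valid rows / variants remain."""


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's estimated effect on one trait.

    ``beta`` is the effect per copy of ``effect_allele`` (SD units for a
    continuous trait, log-odds for a binary one); ``se`` its standard error.
    ``eaf`` is the effect-allele frequency, ``None`` when unreported.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise FormatError(
                f"{self.variant_id}: alleles must be single bases in ACGT, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.variant_id}: effect and other allele identical")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise FormatError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise FormatError(f"{self.variant_id}: pval must lie in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise FormatError(f"{self.variant_id}: eaf must lie in (0, 1), got {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise FormatError(f"{self.variant_id}: n must be positive")
        if not math.isfinite(self.beta):
            raise FormatError(f"{self.variant_id}: beta not finite")
        # published tables round p-values, so |z| vs p consistency is warn-only
        p_implied = 2.0 * stats.norm.sf(abs(self.beta / self.se))
        if p_implied > 1e-300 and not (p_implied / 2 <= self.pval <= min(1.0, p_implied * 2)):
            logger.debug(
                "%s: pval %.3g inconsistent with beta/se (implies %.3g)",
                self.variant_id,
                self.pval,
                p_implied,
            )

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1-eaf)``; None when eaf missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def flipped(self) -> "VariantAssociation":
        """The same association reported on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )


@dataclass
class SummaryStats:
    """An ordered set of variant associations for one trait."""

    trait_name: str
    associations: list[VariantAssociation]
    trait_type: str = "continuous"

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type}")
        if not self.associations:
            raise EmptyInputError(f"{self.trait_name}: no associations")
        ids = [a.variant_id for a in self.associations]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise FormatError(f"{self.trait_name}: duplicate variant ids {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.associations)

    def get(self, variant_id: str) -> VariantAssociation | None:
        return self._index().get(variant_id)

    def _index(self) -> dict[str, VariantAssociation]:
        return {a.variant_id: a for a in self.associations}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": a.variant_id,
                "chrom": a.chrom,
                "pos": a.pos,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "eaf": a.eaf,
                "beta": a.beta,
                "se": a.se,
                "pval": a.pval,
                "n": a.n,
            }
            for a in self.associations
        ]
        return pd.DataFrame(rows)


@dataclass
class LDMatrix:
    """Pairwise r-squared between variants, keyed by variant id."""

    variant_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.variant_ids)
        if len(set(self.variant_ids)) != k:
            raise FormatError("LD matrix: duplicate variant ids")
        if self.r2.shape != (k, k):
            raise FormatError(f"LD matrix: shape {self.r2.shape} does not match {k} ids")
        if np.any(self.r2 < 0) or np.any(self.r2 > 1):
            raise FormatError("LD matrix: r2 values outside [0, 1]")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise FormatError("LD matrix: diagonal must be 1")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise FormatError("LD matrix: not symmetric")
        self._pos = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._pos

    def get(self, a: str, b: str) -> float | None:
        """r2 between two variants, or None when either is absent."""
        ia, ib = self._pos.get(a), self._pos.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])


@dataclass
class ExpressionMatrix:
    """Protein-array intensities (proteins x samples) with case/control labels."""

    protein_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise FormatError("expression matrix: duplicate protein ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("expression matrix: duplicate sample ids")
        if self.values.shape != (len(self.protein_ids), len(self.sample_ids)):
            raise FormatError(
                f"expression matrix: shape {self.values.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.sample_ids)} samples"
            )
        if len(self.group) != len(self.sample_ids):
            raise FormatError("expression matrix: group labels do not match samples")
        bad = set(self.group) - {"case", "control"}
        if bad:
            raise FormatError(f"expression matrix: unknown group labels {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression matrix: non-finite intensities")
        if np.any(self.values < 0):
            raise FormatError("expression matrix: negative intensities")
        g = np.asarray(self.group)
        if (g == "case").sum() < 2 or (g == "control").sum() < 2:
            raise FormatError("expression matrix: both groups need >=2 samples")

    @property
    def case_mask(self) -> np.ndarray:
        return np.asarray(self.group) == "case"

    def row(self, protein_id: str) -> np.ndarray:
        try:
            i = self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"protein {protein_id} not in matrix") from None
        return self.values[i]


# ---------------------------------------------------------------------------
# readers / writers


def _resolve_columns(column_map: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(cols)
        if unknown:
            raise ValueError(f"column_map has unknown fields: {sorted(unknown)}")
        cols.update(column_map)
    return cols


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "continuous",
) -> SummaryStats:
    """Read a summary-statistics TSV into a validated :class:`SummaryStats`.

    Rows failing validation (non-positive SE, out-of-range p or EAF, bad
    alleles) are dropped with a logged count. Mandatory columns: all except
    EAF and N, which may be absent or ``NA``.
    """
    path = Path(path)
    cols = _resolve_columns(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, na_values=[MISSING], keep_default_na=False)
    mandatory = [k for k in cols if k not in ("eaf", "n")]
    for key in mandatory:
        if cols[key] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {cols[key]!r} (field {key})")
    has_eaf = cols["eaf"] in df.columns
    has_n = cols["n"] in df.columns

    assocs: list[VariantAssociation] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            eaf = None
            if has_eaf and pd.notna(row[cols["eaf"]]):
                eaf = float(row[cols["eaf"]])
            n = None
            if has_n and pd.notna(row[cols["n"]]):
                n = int(float(row[cols["n"]]))
            assocs.append(
                VariantAssociation(
                    variant_id=str(row[cols["variant_id"]]),
                    chrom=str(row[cols["chrom"]]),
                    pos=int(float(row[cols["pos"]])),
                    effect_allele=str(row[cols["effect_allele"]]).upper(),
                    other_allele=str(row[cols["other_allele"]]).upper(),
                    eaf=eaf,
                    beta=float(row[cols["beta"]]),
                    se=float(row[cols["se"]]),
                    pval=float(row[cols["pval"]]),
                    n=n,
                )
            )
        except (FormatError, ValueError, TypeError):
            n_dropped += 1
    if n_dropped:
        logger.warning("%s: dropped %d invalid rows", path, n_dropped)
    if not assocs:
        raise EmptyInputError(f"{path}: no valid rows")
    return SummaryStats(
        trait_name=trait_name or path.stem,
        associations=assocs,
        trait_type=trait_type,
    )


def write_sumstats(s: SummaryStats, path: str | Path, column_map: Mapping[str, str] | None = None) -> Path:
    """Write a SummaryStats to TSV so that :func:`read_sumstats` round-trips it."""
    path = Path(path)
    cols = _resolve_columns(column_map)
    order = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# trait_name={s.trait_name}\ttrait_type={s.trait_type}\n")
        fh.write("\t".join(cols[k] for k in order) + "\n")
        for a in s.associations:
            vals = [
                a.variant_id,
                a.chrom,
                str(a.pos),
                a.effect_allele,
                a.other_allele,
                MISSING if a.eaf is None else repr(a.eaf),
                repr(a.beta),
                repr(a.se),
                repr(a.pval),
                MISSING if a.n is None else str(a.n),
            ]
            fh.write("\t".join(vals) + "\n")
    return path


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read a square r2 TSV (ids in first row and first column)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    ids = [str(c) for c in df.columns]
    row_ids = [str(i) for i in df.index]
    if ids != row_ids:
        raise FormatError(f"{path}: row ids do not match column ids")
    return LDMatrix(variant_ids=ids, r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(ld.r2, index=ld.variant_ids, columns=ld.variant_ids).to_csv(path, sep="\t")
    return path


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read an intensity matrix (proteins x samples) plus a sample-group table.

    The group table has two columns ``sample_id`` and ``group`` with labels
    case/control; its sample ids must exactly match the matrix columns.
    """
    mat = pd.read_csv(matrix_path, sep=None, engine="python", comment="#", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", comment="#")
    if not {"sample_id", "group"} <= set(groups.columns):
        raise FormatError(f"{groups_path}: needs columns sample_id, group")
    gmap = dict(zip(groups["sample_id"].astype(str), groups["group"].astype(str)))
    sample_ids = [str(c) for c in mat.columns]
    missing = [s for s in sample_ids if s not in gmap]
    if missing:
        raise FormatError(f"{groups_path}: samples missing from group table: {missing[:5]}")
    extra = set(gmap) - set(sample_ids)
    if extra:
        raise FormatError(f"{groups_path}: group table has unknown samples: {sorted(extra)[:5]}")
    return ExpressionMatrix(
        protein_ids=[str(i) for i in mat.index],
        sample_ids=sample_ids,
        values=mat.to_numpy(dtype=float),
        group=[gmap[s] for s in sample_ids],
    )


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path) -> None:
    pd.DataFrame(m.values, index=m.protein_ids, columns=m.sample_ids).to_csv(matrix_path, sep="\t")
    pd.DataFrame({"sample_id": m.sample_ids, "group": m.group}).to_csv(groups_path, sep="\t", index=False)
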