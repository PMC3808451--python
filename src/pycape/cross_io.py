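"""Reading, writing and curating cross data in the R/qtl "csv" dialect.

The on-disk format is a single comma-separated file: a header row of
phenotype names followed by marker names; a second row that is blank under
the phenotype columns and carries the chromosome label under each marker;
an optional third row of centimorgan positions (blank under phenotypes);
and one row per individual thereafter.  Phenotype columns are identified by
the blank-chromosome convention.

Covariates (sex, treatment, maternal environment, ...) are promoted to
pseudo-markers on chromosome "0" so that every downstream operation treats
them exactly like a genetic locus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Cross",
    "FormatError",
    "ContentError",
    "BACKCROSS_CODES",
    "INTERCROSS_CODES",
    "DEFAULT_MISSING",
    "read_qtl_csv",
    "write_qtl_csv",
    "promote_covariates",
    "drop_redundant_markers",
    "marker_order",
]

#: Genotype code presets.  Backcross: homozygous parental vs heterozygote.
BACKCROSS_CODES = {"A": 0.0, "H": 1.0}
#: Intercross: two homozygotes and the heterozygote at half dose.
INTERCROSS_CODES = {"A": 0.0, "H": 0.5, "B": 1.0}

DEFAULT_MISSING = frozenset({"-", "NA", ""})

COVARIATE_CHROMOSOME = "0"


class FormatError(ValueError):
    """The file does not follow the R/qtl csv layout."""


class ContentError(ValueError):
    """The file parses but its content violates a requirement."""


def _chrom_key(label: str):
    """Sort chromosomes numerically when possible; "0" (covariates) first."""
    try:
        return (0, float(label), "")
    except (TypeError, ValueError):
        return (1, 0.0, str(label))


def marker_order(marker_map: pd.DataFrame) -> list[str]:
    """Marker names ordered by chromosome then position (covariates first).

    ``marker_map`` is indexed by marker name with columns ``chromosome``
    (text label) and ``position`` (cM, may be NaN).  Ordering within a
    chromosome falls back to the existing index order when positions tie or
    are absent.
    """
    df = marker_map.copy()
    df["_ck"] = [_chrom_key(c) for c in df["chromosome"]]
    df["_pos"] = df["position"].fillna(0.0)
    df["_i"] = range(len(df))
    df = df.sort_values(["_ck", "_pos", "_i"], kind="stable")
    return list(df.index)


@dataclass
class Cross:
    """Sample-aligned phenotype and genotype data for a cross.

    Attributes
    ----------
    phenotypes : DataFrame, n_samples x n_phenotypes, real-valued, NaN allowed.
    genotypes : DataFrame, n_samples x n_markers, allele dosage in [0, 1]
        (backcross {0,1}; intercross {0, 0.5, 1}), NaN allowed.
    map : DataFrame indexed by marker name with columns ``chromosome`` and
        ``position`` (cM; NaN when unknown).
    covariate_markers : names of genotype columns that are promoted
        covariates (always on chromosome "0").
    """

    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    map: pd.DataFrame
    covariate_markers: list[str] = field(default_factory=list)

    @property
    def individuals(self) -> list:
        return list(self.phenotypes.index)

    @property
    def n_samples(self) -> int:
        return len(self.phenotypes)

    def validate(self) -> None:
        if len(self.phenotypes) != len(self.genotypes):
            raise ContentError("phenotype and genotype row counts differ")
        if not self.phenotypes.index.equals(self.genotypes.index):
            raise ContentError("phenotype and genotype indexes differ")
        if list(self.genotypes.columns) != list(self.map.index):
            raise ContentError("genotype columns do not match the marker map")
        if self.map.index.has_duplicates:
            dup = self.map.index[self.map.index.duplicated()].tolist()
            raise ContentError(f"duplicate marker names: {dup}")
        g = self.genotypes.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (g < 0) | (g > 1)
        if np.any(bad & ~np.isnan(g)):
            raise ContentError("genotype dosages outside [0, 1]")
        missing_cov = set(self.covariate_markers) - set(self.map.index)
        if missing_cov:
            raise ContentError(f"covariate markers not in map: {sorted(missing_cov)}")

    def copy(self) -> "Cross":
        return Cross(
            self.phenotypes.copy(),
            self.genotypes.copy(),
            self.map.copy(),
            list(self.covariate_markers),
        )


def _parse_float(token: str, missing_codes) -> float:
    tok = token.strip()
    if tok in missing_codes:
        return np.nan
    return float(tok)


def read_qtl_csv(path, genotype_codes: dict[str, float],
                 missing_codes=DEFAULT_MISSING) -> Cross:
    """Read a cross from an R/qtl "csv" file.

    Parameters
    ----------
    path : file path.
    genotype_codes : mapping from genotype token to allele dosage in [0, 1];
        use :data:`BACKCROSS_CODES` or :data:`INTERCROSS_CODES` for the
        standard dialects.  Numeric tokens are accepted as literal dosages.
    missing_codes : tokens treated as missing values.

    Returns
    -------
    Cross with phenotypes/genotypes split by the blank-chromosome
    convention; markers on chromosome "0" are flagged as covariates.

    Raises
    ------
    FormatError : malformed header or ragged rows.
    ContentError : zero phenotypes/markers, or unknown genotype tokens
        (the error lists every offending token and its cell).
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if len(rows) < 3:
        raise FormatError("file too short: need header, chromosome row and data")
    header, chrom_row = rows[0], rows[1]
    width = len(header)
    for i, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise FormatError(f"ragged row {i}: {len(r)} cells, expected {width}")

    blank = [c.strip() == "" for c in chrom_row]
    n_phen = 0
    while n_phen < width and blank[n_phen]:
        n_phen += 1
    if n_phen == 0:
        raise FormatError("no blank-chromosome phenotype block in row 2")
    if any(blank[n_phen:]):
        j = n_phen + blank[n_phen:].index(True)
        raise FormatError(
            f"blank chromosome cell under marker column {header[j]!r}; "
            "phenotypes must form a leading block"
        )
    n_markers = width - n_phen
    if n_markers == 0:
        raise ContentError("no marker columns")

    phen_names = [h.strip() for h in header[:n_phen]]
    marker_names = [h.strip() for h in header[n_phen:]]
    chromosomes = [c.strip() for c in chrom_row[n_phen:]]

    # Optional position row: blank under every phenotype column.
    data_start = 2
    positions = [np.nan] * n_markers
    if len(rows) > 2 and all(c.strip() == "" for c in rows[2][:n_phen]):
        try:
            positions = [_parse_float(c, missing_codes) for c in rows[2][n_phen:]]
        except ValueError as exc:
            raise FormatError(f"unparseable position row: {exc}") from exc
        data_start = 3

    data = rows[data_start:]
    if not data:
        raise ContentError("no individuals (no data rows)")

    phen = np.full((len(data), n_phen), np.nan)
    geno = np.full((len(data), n_markers), np.nan)
    bad_tokens: list[str] = []
    for i, row in enumerate(data):
        for j in range(n_phen):
            try:
                phen[i, j] = _parse_float(row[j], missing_codes)
            except ValueError:
                bad_tokens.append(
                    f"phenotype token {row[j]!r} at row {data_start + i + 1}, "
                    f"column {phen_names[j]!r}"
                )
        for j in range(n_markers):
            tok = row[n_phen + j].strip()
            if tok in missing_codes:
                continue
            if tok in genotype_codes:
                geno[i, j] = genotype_codes[tok]
                continue
            try:
                val = float(tok)
            except ValueError:
                bad_tokens.append(
                    f"genotype token {tok!r} at row {data_start + i + 1}, "
                    f"column {marker_names[j]!r}"
                )
                continue
            if not 0.0 <= val <= 1.0:
                bad_tokens.append(
                    f"genotype dosage {tok!r} outside [0, 1] at row "
                    f"{data_start + i + 1}, column {marker_names[j]!r}"
                )
                continue
            geno[i, j] = val
    if bad_tokens:
        raise ContentError("unknown tokens: " + "; ".join(bad_tokens))

    index = pd.Index([str(i + 1) for i in range(len(data))], name="individual")
    marker_map = pd.DataFrame(
        {"chromosome": chromosomes, "position": positions},
        index=pd.Index(marker_names, name="marker"),
    )
    cross = Cross(
        phenotypes=pd.DataFrame(phen, index=index, columns=phen_names),
        genotypes=pd.DataFrame(geno, index=index, columns=marker_names),
        map=marker_map,
        covariate_markers=[m for m, c in zip(marker_names, chromosomes)
                           if c == COVARIATE_CHROMOSOME],
    )
    cross.validate()
    return cross


def write_qtl_csv(cross: Cross, path, genotype_codes: dict[str, float] | None = None,
                  missing_code: str = "-") -> None:
    """Write a Cross back to R/qtl csv.

    Dosages with an exact entry in ``genotype_codes`` (inverted) are written
    as that token; all other dosages are written numerically so the file
    round-trips through :func:`read_qtl_csv` with the same code map.
    """
    inverse = {}
    if genotype_codes:
        for tok, dose in genotype_codes.items():
            inverse.setdefault(float(dose), tok)

    def fmt_geno(v: float) -> str:
        if np.isnan(v):
            return missing_code
        if v in inverse:
            return inverse[v]
        return repr(float(v))

    def fmt_phen(v: float) -> str:
        return missing_code if np.isnan(v) else repr(float(v))

    n_phen = cross.phenotypes.shape[1]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(cross.phenotypes.columns) + list(cross.genotypes.columns))
        w.writerow([""] * n_phen + [str(c) for c in cross.map["chromosome"]])
        pos = cross.map["position"]
        if pos.notna().any():
            w.writerow([""] * n_phen +
                       ["" if np.isnan(p) else repr(float(p)) for p in pos])
        P = cross.phenotypes.to_numpy(dtype=float)
        G = cross.genotypes.to_numpy(dtype=float)
        for i in range(len(P)):
            w.writerow([fmt_phen(v) for v in P[i]] + [fmt_geno(v) for v in G[i]])


def promote_covariates(cross: Cross, names: list[str]) -> Cross:
    """Move phenotype columns to covariate pseudo-markers on chromosome "0".

    Each named column is removed from the phenotype matrix, min-max rescaled
    to [0, 1] (so it behaves as an allele dosage downstream), appended as a
    genotype column and recorded in ``covariate_markers``.  Sample alignment
    is preserved.
    """
    missing = [n for n in names if n not in cross.phenotypes.columns]
    if missing:
        raise KeyError(f"covariate columns not found among phenotypes: {missing}")
    if cross.phenotypes.shape[1] - len(names) < 2:
        raise ContentError(
            "promoting covariates would leave fewer than 2 phenotypes"
        )
    out = cross.copy()
    new_rows = []
    for k, name in enumerate(names):
        col = out.phenotypes[name].astype(float)
        lo, hi = col.min(skipna=True), col.max(skipna=True)
        if not np.isfinite(lo) or not np.isfinite(hi) or hi == lo:
            raise ContentError(f"covariate {name!r} is constant or all-missing")
        out.genotypes[name] = (col - lo) / (hi - lo)
        new_rows.append((name, COVARIATE_CHROMOSOME, float(k)))
        out.phenotypes = out.phenotypes.drop(columns=[name])
        out.covariate_markers.append(name)
    addition = pd.DataFrame(
        {"chromosome": [r[1] for r in new_rows],
         "position": [r[2] for r in new_rows]},
        index=pd.Index([r[0] for r in new_rows], name="marker"),
    )
    out.map = pd.concat([out.map, addition])
    out.validate()
    return out


def drop_redundant_markers(cross: Cross) -> tuple[Cross, list[str]]:
    """Remove markers fully redundant with the preceding retained marker.

    A marker is dropped when its genotype vector is identical, on jointly
    observed entries (at least one), to the previously retained marker on
    the same chromosome in map order.  The earliest marker of each redundant
    run is kept.  Idempotent.
    """
    order = marker_order(cross.map)
    keep: list[str] = []
    dropped: list[str] = []
    last_kept_by_chrom: dict[str, str] = {}
    G = cross.genotypes
    for name in order:
        chrom = cross.map.at[name, "chromosome"]
        prev = last_kept_by_chrom.get(chrom)
        redundant = False
        if prev is not None:
            a = G[prev].to_numpy(dtype=float)
            b = G[name].to_numpy(dtype=float)
            joint = ~np.isnan(a) & ~np.isnan(b)
            redundant = joint.any() and bool(np.all(a[joint] == b[joint]))
        if redundant:
            dropped.append(name)
        else:
            keep.append(name)
            last_kept_by_chrom[chrom] = name
    # preserve original column order among retained markers
    retained = [m for m in cross.genotypes.columns if m in set(keep)]
    out = replace(
        cross.copy(),
        genotypes=cross.genotypes[retained].copy(),
        map=cross.map.loc[retained].copy(),
        covariate_markers=[m for m in cross.covariate_markers if m in set(keep)],
    )
    return out, dropped
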