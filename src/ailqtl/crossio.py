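"""Cross data I/O and coordinate handling.

Reads and writes experimental-cross data (genotypes on a genetic map plus
phenotypes and covariates) in the single-file R/qtl "csv" layout, keeps the
dual cM / Mb coordinate systems of the genetic map in sync, and derives
growth traits (mass differences) from raw body-mass columns.

Genotypes are stored internally as small integer codes::

    0 = AA   (homozygous for the wild-founder allele)
    1 = AB
    2 = BB   (homozygous for the domestic-founder allele)
    3 = not-AA (partially informative: AB or BB)
    4 = not-BB (partially informative: AA or AB)
   -1 = missing
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# internal genotype alphabet
GENO_AA, GENO_AB, GENO_BB, GENO_NOT_AA, GENO_NOT_BB, GENO_MISSING = 0, 1, 2, 3, 4, -1

#: genotype code -> set of compatible true states (0/1/2)
COMPATIBLE_STATES = {
    GENO_AA: (0,),
    GENO_AB: (1,),
    GENO_BB: (2,),
    GENO_NOT_AA: (1, 2),
    GENO_NOT_BB: (0, 1),
    GENO_MISSING: (0, 1, 2),
}

#: common R/qtl genotype-letter conventions, tried in order during reading
CODE_MAPS = (
    {"A": GENO_AA, "H": GENO_AB, "B": GENO_BB, "C": GENO_NOT_AA, "D": GENO_NOT_BB},
    {"AA": GENO_AA, "AB": GENO_AB, "BB": GENO_BB, "C": GENO_NOT_AA, "D": GENO_NOT_BB},
    {"1": GENO_AA, "2": GENO_AB, "3": GENO_BB, "5": GENO_NOT_AA, "4": GENO_NOT_BB},
)

#: default letters used when writing
DEFAULT_WRITE_CODES = {GENO_AA: "A", GENO_AB: "H", GENO_BB: "B",
                       GENO_NOT_AA: "C", GENO_NOT_BB: "D", GENO_MISSING: "-"}

NA_STRINGS = frozenset({"", "-", "NA", "na", "N/A", "nan"})

MASS_TRAITS = ("w8", "w42", "w112", "w212")
#: growth trait -> (later mass, earlier mass)
GROWTH_DEFS = {
    "g8.42": ("w42", "w8"),
    "g42.112": ("w112", "w42"),
    "g112.212": ("w212", "w112"),
}


class CrossFormatError(ValueError):
    """Raised when a cross file violates the expected R/qtl csv layout."""


@dataclass
class GeneticMap:
    """A marker map with genetic (cM) and optional physical (Mb) coordinates.

    Parameters
    ----------
    markers
        DataFrame indexed by marker name with columns ``chrom`` (str),
        ``cm`` (float) and optionally ``mb`` (float; NaN where unknown).
        Markers must be unique, each on exactly one chromosome, with cM
        positions non-decreasing within a chromosome.
    """

    markers: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.markers
        if m.index.has_duplicates:
            dups = m.index[m.index.duplicated()].tolist()
            raise CrossFormatError(f"duplicate marker names: {dups}")
        m["chrom"] = m["chrom"].astype(str)
        if "mb" not in m.columns:
            m["mb"] = np.nan
        for chrom, sub in m.groupby("chrom", sort=False):
            cm = sub["cm"].to_numpy(float)
            if np.any(np.diff(cm) < 0):
                raise CrossFormatError(f"cM positions not monotone on chromosome {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        # preserve file order
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        sub = self.markers[self.markers["chrom"] == str(chrom)]
        if sub.empty:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return sub

    def chrom_span_cm(self, chrom: str) -> tuple[float, float]:
        cm = self.chrom_markers(chrom)["cm"]
        return float(cm.iloc[0]), float(cm.iloc[-1])

    def _dual_coords(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.chrom_markers(chrom).dropna(subset=["mb"])
        if len(sub) < 2:
            raise ValueError(f"chromosome {chrom}: need >=2 markers with physical "
                             "coordinates for interpolation")
        return sub["cm"].to_numpy(float), sub["mb"].to_numpy(float)

    def cm_to_mb(self, chrom: str, position_cm):
        """Map genetic positions to physical Mb by piecewise-linear interpolation.

        Outside the span of anchored markers the terminal segment's slope is
        extended (clamped extrapolation), floored at 0 Mb.
        """
        cm, mb = self._dual_coords(chrom)
        return _interp_extrap(position_cm, cm, mb)

    def mb_to_cm(self, chrom: str, position_mb):
        """Inverse of :meth:`cm_to_mb` (requires Mb monotone on the chromosome)."""
        cm, mb = self._dual_coords(chrom)
        order = np.argsort(mb, kind="stable")
        return _interp_extrap(position_mb, mb[order], cm[order])


def _interp_extrap(x, xp: np.ndarray, fp: np.ndarray):
    """np.interp plus linear extrapolation from the terminal segments, floored at 0."""
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.interp(x_arr, xp, fp)
    if len(xp) >= 2:
        lo = x_arr < xp[0]
        hi = x_arr > xp[-1]
        slope_lo = (fp[1] - fp[0]) / (xp[1] - xp[0]) if xp[1] > xp[0] else 0.0
        slope_hi = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2]) if xp[-1] > xp[-2] else 0.0
        y[lo] = fp[0] + slope_lo * (x_arr[lo] - xp[0])
        y[hi] = fp[-1] + slope_hi * (x_arr[hi] - xp[-1])
    y = np.maximum(y, 0.0)
    return float(y[0]) if np.isscalar(x) or np.ndim(x) == 0 else y


@dataclass
class Cross:
    """An intercross dataset: map, genotypes, phenotypes and covariates.

    All three tables share one individual index. ``covar`` carries ``sex``
    (values "male"/"female"), ``batch`` and optionally ``dye``.
    """

    gmap: GeneticMap
    geno: pd.DataFrame
    pheno: pd.DataFrame
    covar: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.geno.index.equals(self.pheno.index)
                and self.geno.index.equals(self.covar.index)):
            raise CrossFormatError("genotype/phenotype/covariate tables must share "
                                   "one individual index")
        missing = [m for m in self.gmap.markers.index if m not in self.geno.columns]
        if missing:
            raise CrossFormatError(f"markers missing from genotype table: {missing[:5]}")
        self.geno = self.geno[list(self.gmap.markers.index)].astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return len(self.geno)

    @property
    def n_markers(self) -> int:
        return len(self.gmap.markers)

    def sex_code(self) -> pd.Series:
        """Sex as a numeric covariate: male = +1, female = -1."""
        sex = self.covar["sex"].astype(str)
        bad = ~sex.isin(["male", "female"])
        if bad.any():
            raise ValueError(f"unrecognized sex values: {sorted(sex[bad].unique())}")
        return sex.map({"male": 1.0, "female": -1.0})

    def additive_coded_genotypes(self, impute: bool = True) -> pd.DataFrame:
        """Genotypes as additive dosages in [-1, 1] for PCA-style analyses.

        Partially informative codes get their conditional expectation under
        F2 proportions; missing values are mean-imputed per marker if
        ``impute`` is set.
        """
        mapping = {GENO_AA: -1.0, GENO_AB: 0.0, GENO_BB: 1.0,
                   GENO_NOT_AA: 1.0 / 3.0, GENO_NOT_BB: -1.0 / 3.0,
                   GENO_MISSING: np.nan}
        x = self.geno.apply(lambda col: col.map(mapping))
        if impute:
            x = x.fillna(x.mean())
        return x

    def subset(self, individuals) -> "Cross":
        return Cross(self.gmap, self.geno.loc[individuals].copy(),
                     self.pheno.loc[individuals].copy(),
                     self.covar.loc[individuals].copy(), dict(self.metadata))


# ---------------------------------------------------------------------------
# R/qtl csv reading / writing

def _detect_code_map(tokens: set[str]) -> dict[str, int]:
    observed = {t for t in tokens if t not in NA_STRINGS}
    for cmap in CODE_MAPS:
        if observed <= set(cmap):
            return cmap
    raise CrossFormatError(
        f"could not match genotype codes {sorted(observed)!r} to a known "
        "R/qtl convention (tried A/H/B/C/D, AA/AB/BB and 1/2/3)")


def read_cross_csv(path, covariate_columns=("sex", "batch", "dye"),
                   code_map: dict[str, int] | None = None) -> Cross:
    """Read a single-file R/qtl-format cross CSV.

    Layout: row 1 holds phenotype then marker names; row 2 holds the
    chromosome of each marker (blank under phenotypes); an optional row 3
    holds cM positions; remaining rows are individuals. Genotype letter
    conventions are auto-detected unless ``code_map`` is given.

    Columns named in ``covariate_columns`` (case-insensitive) are moved to
    the covariate table; a column named ``id`` becomes the individual index.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise CrossFormatError("cross csv needs a header, a chromosome row and data")
    header, chrom_row = rows[0], rows[1]
    if len(chrom_row) != len(header):
        raise CrossFormatError("chromosome row length does not match header")
    is_marker = [c.strip() != "" for c in chrom_row]
    if is_marker[0] or not any(is_marker):
        raise CrossFormatError("no phenotype columns before the first marker column "
                               "or chromosome row malformed")
    # first marker column onward must all be markers (R/qtl layout)
    first_marker = is_marker.index(True)
    if not all(is_marker[first_marker:]):
        raise CrossFormatError("marker columns must be contiguous at the right")

    # optional cM row: blank under phenotypes, numeric under markers
    pos_row = rows[2]
    has_pos = (all(pos_row[i].strip() == "" for i in range(first_marker))
               and _all_floats(pos_row[first_marker:]))
    if has_pos:
        cm_positions = [float(v) for v in pos_row[first_marker:]]
        data_rows = rows[3:]
    else:
        cm_positions = None
        data_rows = rows[2:]

    marker_names = [h.strip() for h in header[first_marker:]]
    chroms = [c.strip() for c in chrom_row[first_marker:]]
    if cm_positions is None:
        # fall back to marker order within chromosome, 10 cM spacing
        cm_positions, seen = [], {}
        for c in chroms:
            cm_positions.append(10.0 * seen.get(c, 0))
            seen[c] = seen.get(c, 0) + 1
    gmap = GeneticMap(pd.DataFrame(
        {"chrom": chroms, "cm": cm_positions},
        index=pd.Index(marker_names, name="marker")))

    pheno_names = [h.strip() for h in header[:first_marker]]
    geno_raw = [[v.strip() for v in r[first_marker:]] for r in data_rows]
    tokens = {v for row in geno_raw for v in row}
    cmap = code_map or _detect_code_map(tokens)

    geno = np.full((len(data_rows), len(marker_names)), GENO_MISSING, dtype=np.int8)
    for i, row in enumerate(geno_raw):
        for j, v in enumerate(row):
            if v not in NA_STRINGS:
                geno[i, j] = cmap[v]

    pheno_tab = pd.DataFrame([r[:first_marker] for r in data_rows], columns=pheno_names)
    lower = {c.lower(): c for c in pheno_tab.columns}
    if "id" in lower:
        raw_ids = pheno_tab.pop(lower["id"]).values
        try:
            index = pd.Index([int(v) for v in raw_ids], name="id")
        except ValueError:
            index = pd.Index(raw_ids, name="id")
    else:
        index = pd.RangeIndex(len(data_rows), name="id")
    pheno_tab.index = index

    covar_cols = [lower[c] for c in (c.lower() for c in covariate_columns) if c in lower]
    covar = pheno_tab[covar_cols].copy()
    covar.columns = [c.lower() for c in covar.columns]
    pheno = pheno_tab.drop(columns=covar_cols).apply(
        pd.to_numeric, errors="coerce").astype(float)
    if "sex" in covar.columns:
        covar["sex"] = covar["sex"].str.lower().map(
            lambda s: {"m": "male", "f": "female", "1": "male", "0": "female"}.get(s, s))

    return Cross(gmap, pd.DataFrame(geno, index=index, columns=marker_names),
                 pheno, covar)


def _all_floats(values) -> bool:
    try:
        [float(v) for v in values]
        return True
    except ValueError:
        return False


def write_cross_csv(cross: Cross, path, write_codes: dict[int, str] | None = None) -> None:
    """Write a Cross back to the single-file R/qtl csv layout.

    Output is deterministic: phenotypes in table order, covariates appended
    (sex/batch/dye), markers in map order, three header rows.
    """
    codes = write_codes or DEFAULT_WRITE_CODES
    markers = cross.gmap.markers
    pheno_cols = list(cross.pheno.columns)
    covar_cols = list(cross.covar.columns)
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    left = ["id"] + pheno_cols + covar_cols
    w.writerow(left + list(markers.index))
    w.writerow([""] * len(left) + list(markers["chrom"]))
    w.writerow([""] * len(left) + [f"{c:g}" for c in markers["cm"]])
    geno = cross.geno.to_numpy()
    for i, ind in enumerate(cross.geno.index):
        row = [str(ind)]
        for c in pheno_cols:
            v = cross.pheno.iloc[i][c]
            row.append("" if pd.isna(v) else f"{v:g}")
        for c in covar_cols:
            v = cross.covar.iloc[i][c]
            row.append("" if pd.isna(v) else str(v))
        row.extend(codes[g] for g in geno[i])
        w.writerow(row)
    with open(path, "w", newline="") as fh:
        fh.write(buf.getvalue())


def derive_growth_traits(cross: Cross) -> Cross:
    """Add growth traits as differences of consecutive body-mass columns.

    ``g8.42 = w42 - w8``, ``g42.112 = w112 - w42``, ``g112.212 = w212 - w112``;
    a growth value is missing wherever either mass is. Mass columns are left
    untouched. Early mass itself (w8, hatch) is deliberately never scanned as
    a trait — maternal (egg-size) effects confound it — so only differences
    are exposed for the early phase.
    """
    pheno = cross.pheno.copy()
    for growth, (later, earlier) in GROWTH_DEFS.items():
        if later not in pheno.columns or earlier not in pheno.columns:
            raise KeyError(f"cannot derive {growth}: need {later} and {earlier}")
        pheno[growth] = pheno[later] - pheno[earlier]
    return Cross(cross.gmap, cross.geno.copy(), pheno, cross.covar.copy(),
                 dict(cross.metadata))
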