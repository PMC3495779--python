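"""Data model and file I/O for spatially referenced codominant genotype tables.

The package analyses wind-pollinated, dioecious shrub populations genotyped
at a handful of highly polymorphic microsatellite loci.  Two tables carry
all the data:

* an *adult* table — every reproductive plant in the study plot with its
  sex, planar coordinates in metres, an optional habitat class and a
  diploid multilocus genotype;
* a *progeny* table — seeds collected from a subset of the females
  ("mothers"), each with its own genotype.

Genotypes are stored as integer allele indices into a per-locus allele
catalogue shared between adults and progeny; ``-1`` marks missing data.
A locus genotype is all-or-nothing: single-allele half-calls are rejected
at parse time because microsatellite half-calls are unreliable.

Bearing convention, package-wide: azimuth in degrees clockwise from north;
the direction of a mating event is the azimuth of the vector from the
father (pollen source) to the mother.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pollenflow")

MISSING = -1

RESERVED_ADULT_COLUMNS = ("id", "sex", "x", "y", "habitat")
RESERVED_PROGENY_COLUMNS = ("seed_id", "mother_id")

_SEX_ALIASES = {
    "m": "male", "male": "male", "1": "male",
    "f": "female", "female": "female", "0": "female",
}


class ParseError(ValueError):
    """Raised when an input file violates the genotype-table contract."""


@dataclass
class Locus:
    """A codominant locus: a name and an ordered catalogue of allele labels.

    The catalogue grows as new alleles are encountered during parsing; the
    integer index of a label in ``alleles`` is the internal allele code.
    """

    name: str
    alleles: list = field(default_factory=list)
    missing_code: str = "NA"

    def __post_init__(self) -> None:
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"locus {self.name}: duplicate allele labels")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    def index_of(self, label: str, *, add: bool = False) -> int:
        """Return the integer code of ``label``, optionally cataloguing it."""
        try:
            return self.alleles.index(label)
        except ValueError:
            if not add:
                raise
            self.alleles.append(label)
            return len(self.alleles) - 1


@dataclass
class WindRecord:
    """Wind directions: raw azimuths (deg clockwise from north) or a binned rose."""

    azimuths: np.ndarray | None = None
    bin_edges: np.ndarray | None = None
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.azimuths is not None:
            self.azimuths = np.asarray(self.azimuths, dtype=float) % 360.0
        if self.frequencies is not None:
            self.frequencies = np.asarray(self.frequencies, dtype=float)
            if np.any(self.frequencies < 0):
                raise ValueError("binned wind frequencies must be >= 0")

    def sample_azimuths(self) -> np.ndarray:
        """Raw azimuths, expanding a binned rose to its bin mid-points."""
        if self.azimuths is not None:
            return self.azimuths
        if self.bin_edges is None or self.frequencies is None:
            raise ValueError("empty wind record")
        mids = 0.5 * (np.asarray(self.bin_edges[:-1]) + np.asarray(self.bin_edges[1:]))
        counts = np.round(self.frequencies).astype(int)
        return np.repeat(mids % 360.0, counts)


class SpatialGenotypeTable:
    """Adults of the study plot: id, sex, coordinates, habitat, genotypes.

    Parameters
    ----------
    ids, sex, xy, genotypes
        Parallel arrays; ``genotypes`` has shape ``(n, n_loci, 2)`` holding
        allele indices into ``loci`` (``-1`` = missing, both slots at once).
    loci
        Shared allele catalogue.  Progeny read against this table extend
        the same ``Locus`` objects, so indices remain consistent.
    """

    def __init__(self, ids, sex, xy, genotypes, loci, habitat=None):
        self.ids = np.asarray(ids, dtype=object)
        self.sex = np.asarray(sex, dtype=object)
        self.xy = np.asarray(xy, dtype=float)
        self.genotypes = np.asarray(genotypes, dtype=np.int32)
        self.loci = list(loci)
        self.habitat = None if habitat is None else np.asarray(habitat, dtype=object)
        self._validate()

    def _validate(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            dup = pd.Series(self.ids).value_counts()
            raise ParseError(f"duplicate ids: {list(dup[dup > 1].index)}")
        if self.xy.shape != (n, 2) or not np.all(np.isfinite(self.xy)):
            raise ParseError("coordinates must be finite (n, 2)")
        bad = set(self.sex) - {"male", "female"}
        if bad:
            raise ParseError(f"unknown sex labels: {bad}")
        if self.genotypes.shape != (n, len(self.loci), 2):
            raise ParseError("genotype array shape mismatch")
        half = (self.genotypes == MISSING).sum(axis=2) == 1
        if half.any():
            raise ParseError("single-allele genotype records are not allowed")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list:
        return [loc.name for loc in self.loci]

    def index_of(self, individual_id) -> int:
        idx = np.flatnonzero(self.ids == individual_id)
        if idx.size == 0:
            raise KeyError(individual_id)
        return int(idx[0])

    def males_mask(self) -> np.ndarray:
        return self.sex == "male"

    def females_mask(self) -> np.ndarray:
        return self.sex == "female"

    def subset(self, mask_or_idx) -> "SpatialGenotypeTable":
        idx = np.asarray(mask_or_idx)
        return SpatialGenotypeTable(
            self.ids[idx], self.sex[idx], self.xy[idx], self.genotypes[idx],
            self.loci, None if self.habitat is None else self.habitat[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"id": self.ids, "sex": self.sex,
                "x": self.xy[:, 0], "y": self.xy[:, 1]}
        if self.habitat is not None:
            cols["habitat"] = self.habitat
        df = pd.DataFrame(cols)
        for l, loc in enumerate(self.loci):
            df[loc.name] = [format_genotype(g, loc) for g in self.genotypes[:, l, :]]
        return df


class ProgenyArray:
    """Seeds grouped by mother, genotyped against the adult locus catalogue."""

    def __init__(self, seed_ids, mother_ids, genotypes, loci):
        self.seed_ids = np.asarray(seed_ids, dtype=object)
        self.mother_ids = np.asarray(mother_ids, dtype=object)
        self.genotypes = np.asarray(genotypes, dtype=np.int32)
        self.loci = list(loci)
        if len(set(self.seed_ids)) != len(self.seed_ids):
            raise ParseError("duplicate seed ids")

    def __len__(self) -> int:
        return len(self.seed_ids)

    @property
    def mothers(self) -> list:
        seen: dict = {}
        for m in self.mother_ids:
            seen.setdefault(m, None)
        return list(seen)

    def groups(self) -> dict:
        """Mapping mother id -> integer seed indices, input order preserved."""
        out: dict = {}
        for i, m in enumerate(self.mother_ids):
            out.setdefault(m, []).append(i)
        return {m: np.asarray(v) for m, v in out.items()}

    def n_typed_loci(self) -> np.ndarray:
        return (self.genotypes[:, :, 0] != MISSING).sum(axis=1)

    def subset(self, mask_or_idx) -> "ProgenyArray":
        idx = np.asarray(mask_or_idx)
        return ProgenyArray(self.seed_ids[idx], self.mother_ids[idx],
                            self.genotypes[idx], self.loci)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"seed_id": self.seed_ids, "mother_id": self.mother_ids})
        for l, loc in enumerate(self.loci):
            df[loc.name] = [format_genotype(g, loc) for g in self.genotypes[:, l, :]]
        return df


@dataclass
class AnalysisConfig:
    """All downstream tunables in one place; loadable from YAML.

    Counts must be positive; prior bounds are (low, high) pairs with
    low < high.  Defaults mirror the package's standard workflow.
    """

    min_typed_loci: int = 5
    lod_inbreeding_f: float = 0.0
    tf_override: float | None = None
    tf_n_sim: int = 50000
    kindist_threshold_m: float = 300.0
    sgs_max_distance_m: float = 460.0
    sgs_n_classes: int = 10
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    mcmc_n_iter: int = 100000
    mcmc_burn_in: int = 20000
    mcmc_thin: int = 50
    prior_delta: tuple = (50.0, 1500.0)
    prior_b: tuple = (0.1, 10.0)
    prior_m: tuple = (0.4, 0.95)
    prior_d_ratio: tuple = (1.0, 150.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tf_n_sim", "n_permutations", "n_bootstrap",
                     "mcmc_n_iter", "mcmc_burn_in", "mcmc_thin", "min_typed_loci"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("prior_delta", "prior_b", "prior_m", "prior_d_ratio"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: need low < high, got ({lo}, {hi})")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for k in ("prior_delta", "prior_b", "prior_m", "prior_d_ratio"):
            if k in known:
                known[k] = tuple(known[k])
        unknown = set(raw) - set(known)
        if unknown:
            logger.warning("config: ignoring unknown keys %s", sorted(unknown))
        return cls(**known)


# ---------------------------------------------------------------------------
# genotype token handling

def parse_genotype_token(token: str, locus: Locus, *, line: int | None = None):
    """Parse an ``a/b`` allele-pair token into a pair of allele indices."""
    token = str(token).strip()
    parts = token.split("/")
    if len(parts) != 2 or not parts[0] or not parts[1]:
        where = f" (line {line})" if line is not None else ""
        raise ParseError(
            f"malformed genotype token {token!r} at locus {locus.name}{where}: "
            "expected 'a/b' or 'NA/NA'"
        )
    a, b = (p.strip() for p in parts)
    miss = (a == locus.missing_code, b == locus.missing_code)
    if any(miss):
        if not all(miss):
            where = f" (line {line})" if line is not None else ""
            raise ParseError(
                f"half-missing genotype {token!r} at locus {locus.name}{where}"
            )
        return MISSING, MISSING
    return locus.index_of(a, add=True), locus.index_of(b, add=True)


def format_genotype(pair, locus: Locus) -> str:
    a, b = int(pair[0]), int(pair[1])
    if a == MISSING:
        return f"{locus.missing_code}/{locus.missing_code}"
    return f"{locus.alleles[a]}/{locus.alleles[b]}"


# ---------------------------------------------------------------------------
# readers / writers

def _genotype_block(df: pd.DataFrame, locus_names: Sequence[str],
                    loci: list, offset: int = 2) -> np.ndarray:
    geno = np.full((len(df), len(locus_names), 2), MISSING, dtype=np.int32)
    for l, (name, loc) in enumerate(zip(locus_names, loci)):
        for i, token in enumerate(df[name].astype(str)):
            geno[i, l] = parse_genotype_token(token, loc, line=i + offset)
    return geno


def read_adults(path, fmt: str = "csv", coordinates=None) -> SpatialGenotypeTable:
    """Read the adult table.

    ``fmt='csv'`` expects columns ``id, sex, x, y[, habitat]`` plus one
    column per locus holding ``a/b`` tokens (``NA/NA`` = missing).
    ``fmt='genepop'`` reads a GenePop file for the genotypes and requires a
    companion ``coordinates`` CSV with ``id, sex, x, y[, habitat]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "csv":
        table = _read_adults_csv(path)
    elif fmt == "genepop":
        if coordinates is None:
            raise ValueError("genepop format requires a coordinates CSV")
        table = _read_adults_genepop(path, coordinates)
    else:
        raise ValueError(f"unknown adult-table format {fmt!r}")
    miss = float((table.genotypes[:, :, 0] == MISSING).mean())
    logger.info("read %d adults, %d loci, %.1f%% missing genotypes from %s",
                len(table), table.n_loci, 100 * miss, path)
    return table


def _read_adults_csv(path: Path) -> SpatialGenotypeTable:
    df = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    for col in ("id", "sex", "x", "y"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    locus_names = [c for c in df.columns if c not in RESERVED_ADULT_COLUMNS]
    if not locus_names:
        raise ParseError(f"{path}: no locus columns found")
    loci = [Locus(name) for name in locus_names]
    sex = np.array([_SEX_ALIASES.get(s.strip().lower()) for s in df["sex"]],
                   dtype=object)
    if any(s is None for s in sex):
        raise ParseError(f"{path}: unrecognized sex label")
    xy = df[["x", "y"]].astype(float).to_numpy()
    habitat = df["habitat"].to_numpy(dtype=object) if "habitat" in df.columns else None
    geno = _genotype_block(df, locus_names, loci)
    return SpatialGenotypeTable(df["id"].str.strip().to_numpy(dtype=object),
                                sex, xy, geno, loci, habitat)


_GENEPOP_ALLELE = re.compile(r"^\d+$")


def _read_adults_genepop(path: Path, coordinates) -> SpatialGenotypeTable:
    """GenePop dialect reader (single population, 2- or 3-digit allele codes)."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GenePop file")
    body = lines[1:]
    pop_idx = next((i for i, ln in enumerate(body) if ln.strip().lower() == "pop"),
                   None)
    if pop_idx is None:
        raise ParseError(f"{path}: no 'Pop' line found")
    locus_names: list = []
    for ln in body[:pop_idx]:
        locus_names.extend(t.strip() for t in ln.split(",") if t.strip())
    loci = [Locus(name) for name in locus_names]
    ids, rows = [], []
    for k, ln in enumerate(body[pop_idx + 1:]):
        if not ln.strip():
            continue
        if ln.strip().lower() == "pop":
            raise ParseError(f"{path}: multiple populations not supported")
        if "," not in ln:
            raise ParseError(f"{path}: malformed GenePop record {ln!r}")
        ind_id, geno_part = ln.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}: individual {ind_id.strip()!r} has {len(tokens)} "
                f"genotypes, expected {len(loci)}")
        row = np.full((len(loci), 2), MISSING, dtype=np.int32)
        for l, tok in enumerate(tokens):
            if not _GENEPOP_ALLELE.match(tok) or len(tok) not in (4, 6):
                raise ParseError(f"{path}: bad GenePop token {tok!r} "
                                 f"(individual {ind_id.strip()!r})")
            w = len(tok) // 2
            a, b = tok[:w], tok[w:]
            if int(a) == 0 or int(b) == 0:
                if int(a) != 0 or int(b) != 0:
                    raise ParseError(f"{path}: half-missing token {tok!r}")
                continue
            row[l, 0] = loci[l].index_of(str(int(a)), add=True)
            row[l, 1] = loci[l].index_of(str(int(b)), add=True)
        ids.append(ind_id.strip())
        rows.append(row)
    geno = np.stack(rows)
    coords = pd.read_csv(coordinates, dtype=str).rename(columns=str.strip)
    coords = coords.set_index(coords["id"].str.strip())
    missing_ids = [i for i in ids if i not in coords.index]
    if missing_ids:
        raise ParseError(f"coordinates file lacks ids: {missing_ids}")
    sel = coords.loc[ids]
    sex = np.array([_SEX_ALIASES.get(str(s).strip().lower()) for s in sel["sex"]],
                   dtype=object)
    xy = sel[["x", "y"]].astype(float).to_numpy()
    habitat = sel["habitat"].to_numpy(dtype=object) if "habitat" in sel.columns else None
    return SpatialGenotypeTable(np.asarray(ids, dtype=object), sex, xy, geno,
                                loci, habitat)


def read_progeny(path, adults: SpatialGenotypeTable,
                 min_typed_loci: int = 5) -> tuple:
    """Read the progeny CSV against a loaded adult table.

    Returns ``(array, flagged)`` where ``flagged`` is a boolean mask of seeds
    typed at fewer than ``min_typed_loci`` loci (kept in the array; callers
    exclude them from likelihood analyses).  Mother ids must resolve to
    females of the adult table.  New alleles are added to the shared
    catalogue so that adult and progeny indices stay consistent.
    """
    try:
        df = pd.read_csv(path, dtype=str).rename(columns=str.strip)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        logger.warning("progeny file %s is empty", path)
        empty = np.empty((0, adults.n_loci, 2), dtype=np.int32)
        return ProgenyArray([], [], empty, adults.loci), np.zeros(0, dtype=bool)
    for col in RESERVED_PROGENY_COLUMNS:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    known = set(df.columns) & set(adults.locus_names)
    if known != set(adults.locus_names):
        raise ParseError(f"{path}: locus columns do not match the adult table")
    mothers = df["mother_id"].str.strip()
    female_ids = set(adults.ids[adults.females_mask()])
    orphans = sorted(set(mothers) - female_ids)
    if orphans:
        raise ParseError(f"{path}: mother ids not found among adult females: "
                         f"{orphans}")
    geno = _genotype_block(df, adults.locus_names, adults.loci)
    arr = ProgenyArray(df["seed_id"].str.strip().to_numpy(dtype=object),
                       mothers.to_numpy(dtype=object), geno, adults.loci)
    flagged = arr.n_typed_loci() < min_typed_loci
    if flagged.any():
        logger.info("%d seeds typed at < %d loci flagged for exclusion",
                    int(flagged.sum()), min_typed_loci)
    logger.info("read %d seeds from %d mothers", len(arr), len(arr.mothers))
    return arr, flagged


def write_adults(table: SpatialGenotypeTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def write_progeny(progeny: ProgenyArray, path) -> None:
    progeny.to_dataframe().to_csv(path, index=False)


def read_wind(path) -> WindRecord:
    """Read wind directions from a CSV with either an ``azimuth`` column or
    ``bin_start, bin_end, frequency`` columns."""
    df = pd.read_csv(path)
    if "azimuth" in df.columns:
        return WindRecord(azimuths=df["azimuth"].astype(float).to_numpy())
    needed = {"bin_start", "bin_end", "frequency"}
    if not needed <= set(df.columns):
        raise ParseError(f"{path}: expected 'azimuth' or {sorted(needed)} columns")
    edges = np.append(df["bin_start"].to_numpy(float), df["bin_end"].iloc[-1])
    return WindRecord(bin_edges=edges, frequencies=df["frequency"].to_numpy(float))


# ---------------------------------------------------------------------------
# geometry helpers

def pairwise_distances(xy_a: np.ndarray, xy_b: np.ndarray | None = None) -> np.ndarray:
    a = np.asarray(xy_a, dtype=float)
    b = a if xy_b is None else np.asarray(xy_b, dtype=float)
    d = a[:, None, :] - b[None, :, :]
    return np.hypot(d[..., 0], d[..., 1])


def bearing_deg(xy_from: np.ndarray, xy_to: np.ndarray) -> np.ndarray:
    """Azimuth (deg clockwise from north) of the vector from ``xy_from`` to
    ``xy_to``; for a mating event pass father first, mother second."""
    src = np.atleast_2d(np.asarray(xy_from, dtype=float))
    dst = np.atleast_2d(np.asarray(xy_to, dtype=float))
    dx = dst[:, 0] - src[:, 0]
    dy = dst[:, 1] - src[:, 1]
    az = np.degrees(np.arctan2(dx, dy)) % 360.0
    return az if az.size > 1 else float(az[0])
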