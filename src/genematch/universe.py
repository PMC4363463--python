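"""Gene-covariate tables, gene sets, and the filters that define analysis universes.

The central object is :class:`GeneUniverse`, an ordered, duplicate-free
collection of :class:`GeneRecord`. Records carry a log2 expression value,
optional log2 coding-sequence and transcript lengths, an optional CLIP tag
count, and arbitrary membership flags. Covariates that are unknown are stored
as ``None`` — never as 0 or a sentinel — and every operation that needs a
covariate says so explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Covariate names usable in :func:`filter_universe` / :func:`select_top_by`.
COVARIATES = ("log_expr", "cds_len_log2", "tx_len_log2", "clip_count")

#: Default header names for the tab-separated gene table.
DEFAULT_COLUMNS = {
    "symbol": "symbol",
    "log_expr": "logCPM",
    "cds_length": "cds_length",
    "tx_length": "tx_length",
    "clip_count": "clip_count",
}


class GeneTableError(ValueError):
    """Configuration or content problem with a gene table or gene set file."""


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol; applied before any set operation."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneRecord:
    """One gene with its covariates; missing covariates are ``None``."""

    symbol: str
    log_expr: float | None = None
    cds_len_log2: float | None = None
    tx_len_log2: float | None = None
    clip_count: int | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("GeneRecord requires a non-empty symbol")
        for name in ("cds_len_log2", "tx_len_log2"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be finite and > 0 (length >= 2 nt), got {v!r}")
        if self.clip_count is not None and self.clip_count < 0:
            raise ValueError(f"clip_count must be >= 0, got {self.clip_count!r}")

    def get(self, covariate: str) -> float | None:
        if covariate not in COVARIATES:
            raise KeyError(f"unknown covariate {covariate!r}; expected one of {COVARIATES}")
        return getattr(self, covariate)


@dataclass(frozen=True)
class GeneSet:
    """A named set of normalized gene symbols."""

    name: str
    symbols: frozenset[str]

    @classmethod
    def from_symbols(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        normalized = frozenset(normalize_symbol(s) for s in symbols if s.strip())
        return cls(name=name, symbols=normalized)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols

    def intersect(self, other: Iterable[str]) -> frozenset[str]:
        return self.symbols & frozenset(normalize_symbol(s) for s in other)


class GeneUniverse:
    """Ordered collection of gene records with stable, duplicate-free symbols.

    Filtering preserves input order, so downstream tie-breaking ("first
    occurrence wins") is deterministic.
    """

    def __init__(self, records: Sequence[GeneRecord], provenance: Sequence[str] = ()) -> None:
        seen: set[str] = set()
        for r in records:
            if r.symbol in seen:
                raise ValueError(f"duplicate symbol in universe: {r.symbol!r}")
            seen.add(r.symbol)
        self._records: tuple[GeneRecord, ...] = tuple(records)
        self._index: dict[str, int] = {r.symbol: i for i, r in enumerate(self._records)}
        self.provenance: tuple[str, ...] = tuple(provenance)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> GeneRecord:
        return self._records[i]

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneUniverse):
            return NotImplemented
        return self._records == other._records

    @property
    def records(self) -> tuple[GeneRecord, ...]:
        return self._records

    @property
    def symbols(self) -> tuple[str, ...]:
        return tuple(r.symbol for r in self._records)

    def symbol_set(self, name: str = "universe") -> GeneSet:
        return GeneSet(name=name, symbols=frozenset(self._index))

    def record(self, symbol: str) -> GeneRecord:
        return self._records[self._index[normalize_symbol(symbol)]]

    def covariate(self, name: str, allow_missing: bool = False) -> np.ndarray:
        """Covariate values aligned to universe order.

        With ``allow_missing`` the result is a float array with NaN for absent
        values; otherwise any absent value raises.
        """
        values = [r.get(name) for r in self._records]
        if not allow_missing:
            missing = sum(v is None for v in values)
            if missing:
                raise ValueError(f"covariate {name!r} missing for {missing} records")
            return np.asarray(values, dtype=float)
        return np.asarray([np.nan if v is None else float(v) for v in values], dtype=float)

    def with_flag(self, flag: str, members: GeneSet) -> "GeneUniverse":
        """Return a universe where records in ``members`` carry ``flag``."""
        new = [
            replace(r, flags=r.flags | {flag}) if r.symbol in members.symbols else r
            for r in self._records
        ]
        return GeneUniverse(new, self.provenance + (f"flag {flag!r} from set {members.name!r}",))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "symbol": self.symbols,
                "log_expr": self.covariate("log_expr", allow_missing=True),
                "cds_len_log2": self.covariate("cds_len_log2", allow_missing=True),
                "tx_len_log2": self.covariate("tx_len_log2", allow_missing=True),
                "clip_count": self.covariate("clip_count", allow_missing=True),
            }
        )


# ---------------------------------------------------------------------------
# I/O


def read_gene_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    log_transform_lengths: bool = False,
) -> GeneUniverse:
    """Read a tab-separated gene table into a :class:`GeneUniverse`.

    Parameters
    ----------
    path:
        TSV file with a header row.
    column_map:
        Maps the roles ``symbol``, ``log_expr``, ``cds_length``, ``tx_length``,
        ``clip_count`` to column names; defaults to :data:`DEFAULT_COLUMNS`.
        ``cds_length``, ``tx_length`` and ``clip_count`` columns are optional.
    log_transform_lengths:
        If true, length columns hold raw nucleotide lengths and are log2
        transformed on ingestion; otherwise they are taken as already log2.

    Rows whose symbol or expression cannot be parsed are dropped (count
    logged). A non-numeric or missing value in an optional column leaves that
    covariate absent but keeps the record. Duplicate symbols keep the first
    occurrence (count logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene table not found: {path}")
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str)
    for role in ("symbol", "log_expr"):
        if cmap[role] not in df.columns:
            raise GeneTableError(
                f"required column {cmap[role]!r} (role {role!r}) not found in {path.name}; "
                f"available: {list(df.columns)}"
            )

    def numeric(role: str) -> pd.Series | None:
        col = cmap[role]
        if col not in df.columns:
            return None
        return pd.to_numeric(df[col], errors="coerce")

    symbols = df[cmap["symbol"]].map(lambda s: normalize_symbol(s) if isinstance(s, str) else "")
    log_expr = pd.to_numeric(df[cmap["log_expr"]], errors="coerce")
    cds = numeric("cds_length")
    tx = numeric("tx_length")
    clip = numeric("clip_count")

    if log_transform_lengths:
        cds = np.log2(cds.where(cds > 0)) if cds is not None else None
        tx = np.log2(tx.where(tx > 0)) if tx is not None else None

    records: list[GeneRecord] = []
    seen: set[str] = set()
    n_dropped = n_dup = 0
    for i in range(len(df)):
        sym = symbols.iloc[i]
        expr = log_expr.iloc[i]
        if not sym or not np.isfinite(expr):
            n_dropped += 1
            continue
        if sym in seen:
            n_dup += 1
            continue
        seen.add(sym)

        def opt(series: pd.Series | None) -> float | None:
            if series is None:
                return None
            v = series.iloc[i]
            return float(v) if np.isfinite(v) else None

        clip_v = opt(clip)
        records.append(
            GeneRecord(
                symbol=sym,
                log_expr=float(expr),
                cds_len_log2=opt(cds),
                tx_len_log2=opt(tx),
                clip_count=None if clip_v is None else int(round(clip_v)),
            )
        )
    if n_dropped:
        logger.warning("%s: dropped %d rows with unparseable symbol/expression", path.name, n_dropped)
    if n_dup:
        logger.warning("%s: dropped %d duplicate symbols (first occurrence kept)", path.name, n_dup)
    return GeneUniverse(records, provenance=(f"read {len(records)} records from {path}",))


def write_gene_table(universe: GeneUniverse, path: str | Path) -> None:
    """Write the standard TSV so tables round-trip through :func:`read_gene_table`."""
    df = universe.to_frame().rename(
        columns={
            "log_expr": DEFAULT_COLUMNS["log_expr"],
            "cds_len_log2": DEFAULT_COLUMNS["cds_length"],
            "tx_len_log2": DEFAULT_COLUMNS["tx_length"],
            "clip_count": DEFAULT_COLUMNS["clip_count"],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene set; '#' comments and blank lines ignored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene set file not found: {path}")
    symbols = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.append(line)
    gs = GeneSet.from_symbols(name or path.stem, symbols)
    if not gs.symbols:
        raise GeneTableError(f"gene set {path} is empty after parsing; cannot be tested")
    return gs


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in sorted(gene_set.symbols)))


# ---------------------------------------------------------------------------
# Filters and selections


def filter_universe(
    universe: GeneUniverse,
    min_log_expr: float | None = None,
    require_cds_len: bool = False,
    require_tx_len: bool = False,
    min_clip_count: int | None = None,
) -> GeneUniverse:
    """Filter a universe, preserving record order.

    ``min_log_expr`` is a strict threshold (kept iff ``log_expr > min_log_expr``);
    ``min_clip_count`` keeps records with ``clip_count >= min_clip_count``
    (absent counts never pass). Raises if the result is empty.
    """
    if len(universe) == 0:
        raise ValueError("cannot filter an empty universe")

    def keep(r: GeneRecord) -> bool:
        if min_log_expr is not None and not (r.log_expr is not None and r.log_expr > min_log_expr):
            return False
        if require_cds_len and r.cds_len_log2 is None:
            return False
        if require_tx_len and r.tx_len_log2 is None:
            return False
        if min_clip_count is not None and not (
            r.clip_count is not None and r.clip_count >= min_clip_count
        ):
            return False
        return True

    kept = [r for r in universe if keep(r)]
    if not kept:
        raise ValueError("filter removed every record")
    desc = (
        f"filter(min_log_expr={min_log_expr}, require_cds_len={require_cds_len}, "
        f"require_tx_len={require_tx_len}, min_clip_count={min_clip_count}) -> {len(kept)} records"
    )
    return GeneUniverse(kept, provenance=universe.provenance + (desc,))


def select_top_by(
    universe: GeneUniverse,
    covariate: str | Sequence[float],
    n: int,
    name: str | None = None,
) -> GeneSet:
    """The ``n`` genes with the largest covariate values.

    ``covariate`` is a covariate name or a value sequence aligned to the
    universe (used e.g. for sampling weights). Ties at the cutoff are broken
    by universe order, first occurrence first.
    """
    if n > len(universe):
        raise ValueError(f"cannot select top {n} from a universe of {len(universe)}")
    if isinstance(covariate, str):
        values = universe.covariate(covariate)
        label = covariate
    else:
        values = np.asarray(covariate, dtype=float)
        if values.shape != (len(universe),):
            raise ValueError("covariate values must align to the universe")
        label = "values"
    order = np.argsort(-values, kind="stable")[:n]
    symbols = [universe[i].symbol for i in sorted(order)]
    return GeneSet.from_symbols(name or f"top{n}_{label}", symbols)
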