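"""Reading, validating, filtering and writing GWAS summary statistics.

The in-memory container is :class:`ZPanel`: per-SNP z-statistics (with
optional beta/se/MAF), a single GWAS sample size, and trait metadata.
Input is delimited text (TSV/CSV/whitespace, optionally gzipped) with a
header; column names are resolved case-insensitively through a synonym
table because summary-statistic formats vary widely between consortia.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Z_BETA_TOL = 1e-8  # consistency tolerance between z and beta/se


class SummaryFormatError(ValueError):
    """Input file lacks the columns needed to build a panel."""


class EmptyPanelError(ValueError):
    """No usable rows survived ingestion or filtering."""


class SNPRecord(NamedTuple):
    """One SNP's summary statistics (z is always populated)."""

    id: str
    z: float
    beta: float | None = None
    se: float | None = None
    maf: float | None = None


@dataclass(frozen=True)
class ZPanel:
    """Ordered per-SNP summary statistics plus trait metadata.

    Vector fields are aligned numpy arrays; ``ids`` may be ``None`` for
    synthetic panels, in which case positional identifiers are generated
    on demand.
    """

    z: np.ndarray
    n: int
    trait_type: str = "continuous"
    prevalence: float | None = None
    ids: np.ndarray | None = None
    beta: np.ndarray | None = None
    se: np.ndarray | None = None
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        if self.n < 3:
            raise ValueError("GWAS sample size n must be >= 3")
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.prevalence is None or not (0.0 < self.prevalence < 1.0):
                raise ValueError("binary trait requires prevalence in (0, 1)")
            for name in ("beta", "se", "maf"):
                if getattr(self, name) is None:
                    raise ValueError(f"binary trait panel requires per-SNP {name}")
        for name in ("beta", "se", "maf"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                object.__setattr__(self, name, v)
                if v.shape != z.shape:
                    raise ValueError(f"{name} not aligned with z")
        if self.se is not None and np.any(self.se[np.isfinite(self.se)] <= 0):
            raise ValueError("se must be > 0 where present")
        if self.ids is not None:
            ids = np.asarray(self.ids)
            object.__setattr__(self, "ids", ids)
            if ids.shape != z.shape:
                raise ValueError("ids not aligned with z")
            if pd.Index(ids).has_duplicates:
                raise ValueError("record ids must be unique")

    @property
    def k(self) -> int:
        """Number of SNPs."""
        return int(self.z.size)

    def record_ids(self) -> np.ndarray:
        if self.ids is not None:
            return self.ids
        return np.array([f"snp{i + 1}" for i in range(self.k)])

    @property
    def records(self) -> Iterator[SNPRecord]:
        ids = self.record_ids()
        for i in range(self.k):
            yield SNPRecord(
                id=str(ids[i]),
                z=float(self.z[i]),
                beta=None if self.beta is None else float(self.beta[i]),
                se=None if self.se is None else float(self.se[i]),
                maf=None if self.maf is None else float(self.maf[i]),
            )

    def subset(self, index: np.ndarray) -> "ZPanel":
        """Panel restricted to the given positional index (order kept)."""
        pick = lambda v: None if v is None else v[index]
        return ZPanel(z=self.z[index], n=self.n, trait_type=self.trait_type,
                      prevalence=self.prevalence, ids=pick(self.ids),
                      beta=pick(self.beta), se=pick(self.se), maf=pick(self.maf))

    def with_z(self, z: np.ndarray) -> "ZPanel":
        """Panel with z replaced (beta rescaled through se when present)."""
        z = np.asarray(z, dtype=float)
        beta = None if self.se is None else z * self.se
        return ZPanel(z=z, n=self.n, trait_type=self.trait_type,
                      prevalence=self.prevalence, ids=self.ids,
                      beta=beta, se=self.se, maf=self.maf)


_SYNONYMS = {
    "id": ("snp", "id", "rsid", "marker", "markername", "variant_id", "snpid"),
    "z": ("z", "zscore", "z_score", "zstat"),
    "beta": ("beta", "b", "effect", "log_odds", "logor"),
    "se": ("se", "standard_error", "stderr", "se_beta"),
    "maf": ("maf", "freq", "eaf", "af", "a1freq", "effect_allele_frequency"),
    "n": ("n", "n_eff", "neff", "samplesize", "n_total"),
}


def _resolve_columns(columns: list[str], overrides: dict[str, str] | None) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    overrides = overrides or {}
    for field, names in _SYNONYMS.items():
        if field in overrides:
            if overrides[field] not in columns:
                raise SummaryFormatError(f"column {overrides[field]!r} (for {field}) not in file")
            resolved[field] = overrides[field]
            continue
        for name in names:
            if name in lower:
                resolved[field] = lower[name]
                break
    return resolved


def read_summary(path, n: int | None = None, trait_type: str = "continuous",
                 prevalence: float | None = None, delimiter: str | None = None,
                 columns: dict[str, str] | None = None) -> ZPanel:
    """Read a delimited summary-statistics file into a :class:`ZPanel`.

    The file must contain either a z column or both beta and se columns
    (z is then computed as beta/se).  ``n`` may come from an ``n`` column
    (the panel uses its median) or must be supplied here.  Rows with
    non-finite z, non-positive se, out-of-range MAF or duplicate ids are
    dropped with logged counts rather than raising.

    ``columns`` optionally maps field names (``z``, ``beta``, ``se``,
    ``maf``, ``id``, ``n``) to actual column names, overriding the
    built-in case-insensitive synonym table.
    """
    sep = delimiter if delimiter is not None else None
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    if df.shape[1] == 1 and sep is None:
        df = pd.read_csv(path, sep=r"\s+", comment="#")
    cols = _resolve_columns(list(df.columns), columns)

    if "z" not in cols and not ("beta" in cols and "se" in cols):
        raise SummaryFormatError(
            "need a z column or both beta and se columns; found "
            f"{list(df.columns)}")

    out = pd.DataFrame(index=df.index)
    out["id"] = (df[cols["id"]].astype(str) if "id" in cols
                 else [f"row{i + 1}" for i in range(len(df))])
    for f in ("z", "beta", "se", "maf", "n"):
        if f in cols:
            out[f] = pd.to_numeric(df[cols[f]], errors="coerce")

    n_raw = len(out)
    if "se" in out:
        bad_se = out["se"].notna() & (out["se"] <= 0)
        if bad_se.any():
            logger.warning("dropping %d rows with se <= 0", int(bad_se.sum()))
            out = out[~bad_se]
    if "z" not in out:
        out["z"] = out["beta"] / out["se"]
    else:
        fill = out["z"].isna()
        if fill.any() and "beta" in out and "se" in out:
            out.loc[fill, "z"] = out.loc[fill, "beta"] / out.loc[fill, "se"]
        if "beta" in out and "se" in out:
            both = out["z"].notna() & out["beta"].notna() & out["se"].notna()
            mism = np.abs(out.loc[both, "z"] - out.loc[both, "beta"] / out.loc[both, "se"])
            n_mism = int((mism > Z_BETA_TOL).sum())
            if n_mism:
                logger.warning("%d rows have |z - beta/se| > %.0e", n_mism, Z_BETA_TOL)

    bad_z = ~np.isfinite(out["z"].to_numpy(dtype=float))
    if bad_z.any():
        logger.warning("dropping %d rows with non-finite z", int(bad_z.sum()))
        out = out[~bad_z]
    if "maf" in out:
        # fold effect-allele frequencies onto the minor allele
        out.loc[out["maf"].notna() & (out["maf"] > 0.5), "maf"] = \
            1.0 - out.loc[out["maf"].notna() & (out["maf"] > 0.5), "maf"]
        bad_maf = out["maf"].notna() & ~((out["maf"] > 0) & (out["maf"] <= 0.5))
        if bad_maf.any():
            logger.warning("dropping %d rows with MAF outside (0, 0.5]", int(bad_maf.sum()))
            out = out[~bad_maf]
    dup = out["id"].duplicated(keep="first")
    if dup.any():
        logger.warning("dropping %d duplicate-id rows (first occurrence kept)", int(dup.sum()))
        out = out[~dup]
    if len(out) == 0:
        raise EmptyPanelError(f"no usable rows in {path} ({n_raw} read)")

    if n is None:
        if "n" not in out or out["n"].isna().all():
            raise ValueError("sample size n not supplied and no n column present")
        n_col = out["n"].dropna()
        n = int(round(float(n_col.median())))
        if n_col.size and float(n_col.max() - n_col.min()) > 0.1 * n:
            logger.warning("per-SNP n ranges over >10%% of the median (%d); "
                           "the conversion uses the single panel-level n", n)

    get = lambda f: out[f].to_numpy(dtype=float) if f in out else None
    return ZPanel(z=out["z"].to_numpy(dtype=float), n=int(n),
                  trait_type=trait_type, prevalence=prevalence,
                  ids=out["id"].to_numpy(), beta=get("beta"),
                  se=get("se"), maf=get("maf"))


def filter_maf(panel: ZPanel, threshold: float, keep_missing: bool = False) -> ZPanel:
    """Keep records with MAF strictly above ``threshold``.

    Records without a MAF are kept only for continuous-trait panels with
    ``keep_missing=True``; otherwise they are dropped.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    if panel.maf is None:
        if panel.trait_type == "continuous" and keep_missing:
            return panel
        raise EmptyPanelError("panel has no MAF column and keep_missing is not allowed")
    has = np.isfinite(panel.maf)
    keep = has & (panel.maf > threshold)
    if keep_missing and panel.trait_type == "continuous":
        keep |= ~has
    dropped = panel.k - int(keep.sum())
    if dropped:
        logger.info("filter_maf: dropped %d of %d records", dropped, panel.k)
    if not keep.any():
        raise EmptyPanelError("MAF filter removed every record")
    return panel.subset(np.flatnonzero(keep))


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonify(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(result, path, format: str = "json", meta: dict | None = None) -> None:
    """Serialise a result object (any package dataclass, dict or DataFrame).

    JSON preserves full float precision (repr round-trip, >= 17 significant
    digits).  TSV flattens a dataclass/dict to two columns, or writes a
    DataFrame as-is; ``meta`` entries are embedded (JSON) or prepended as
    ``#`` comment lines (TSV).
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    if format == "json":
        payload = _jsonify(result)
        if meta:
            payload = {"_meta": _jsonify(meta), **(payload if isinstance(payload, dict)
                                                   else {"value": payload})}
        with opener(path, "wt") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        with opener(path, "wt") as fh:
            for key, val in (meta or {}).items():
                fh.write(f"# {key}={val}\n")
            if isinstance(result, pd.DataFrame):
                result.to_csv(fh, sep="\t", index=False)
            else:
                flat = _jsonify(result)
                fh.write("field\tvalue\n")
                for key, val in flat.items():
                    fh.write(f"{key}\t{json.dumps(val)}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
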