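"""Summary-statistics data model, I/O, and allele harmonization.

GWAS and eQTL association records are carried as pandas DataFrames in a
fixed tab-separated dialect with columns

    snp, chr, pos, ea, oa, eaf, beta, se, p, n

where ``ea``/``oa`` are the effect and other allele, ``eaf`` the
effect-allele frequency, ``beta`` the per-allele effect (log-odds for a
binary trait, expression units for an eQTL) and ``n`` the sample size.
Coordinates are 1-based; genomic windows are closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

#: canonical column order of the summary-statistics dialect
COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: harmonization actions
KEPT = "kept_as_is"
FLIPPED = "outcome_flipped"
DROPPED_PALINDROMIC = "dropped_palindromic"
DROPPED_MISMATCH = "dropped_allele_mismatch"


@dataclass(frozen=True)
class GeneRegion:
    """A gene body on one chromosome, 1-based inclusive coordinates."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )


class ReadResult(NamedTuple):
    """Valid records plus a per-row rejection log."""

    data: pd.DataFrame
    rejected: pd.DataFrame


class HarmonizeResult(NamedTuple):
    """Harmonized pairs (kept rows only) plus the full action audit."""

    pairs: pd.DataFrame
    audit: pd.DataFrame


class SumstatsFormatError(ValueError):
    """A structural problem with an input file (e.g. missing column)."""


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the allele pair is strand-ambiguous ({A,T} or {C,G})."""
    return {effect_allele, other_allele} in ({"A", "T"}, {"C", "G"})


def _row_problem(row: pd.Series) -> str | None:
    """Reason the record violates an invariant, or None if valid."""
    for col in ("pos", "eaf", "beta", "se", "p", "n"):
        if pd.isna(row[col]):
            return f"unparsable {col}"
    if row["ea"] not in _NUCLEOTIDES or row["oa"] not in _NUCLEOTIDES:
        return "allele not in {A,C,G,T}"
    if row["ea"] == row["oa"]:
        return "effect allele equals other allele"
    if row["se"] <= 0:
        return "se<=0"
    if not 0 < row["eaf"] < 1:
        return "eaf out of (0,1)"
    if not 0 < row["p"] <= 1:
        return "p out of (0,1]"
    if row["n"] <= 1:
        return "n<=1"
    return None


def validate_sumstats(df: pd.DataFrame) -> ReadResult:
    """Split a raw table into valid records and rejected rows with reasons.

    Row order is preserved within both outputs.
    """
    reasons = df.apply(_row_problem, axis=1) if len(df) else pd.Series(dtype=object)
    bad = reasons.notna() if len(df) else pd.Series(dtype=bool)
    rejected = df.loc[bad].copy() if len(df) else df.copy()
    rejected["reason"] = reasons[bad] if len(df) else []
    data = df.loc[~bad].copy() if len(df) else df.copy()
    return ReadResult(data.reset_index(drop=True), rejected.reset_index(drop=True))


def read_sumstats(
    path, column_map: Mapping[str, str] | None = None
) -> ReadResult:
    """Read a tab-separated summary-statistics file.

    Parameters
    ----------
    path
        TSV file with a header row.
    column_map
        Optional mapping from canonical names (``snp``, ``chr``, ...) to
        the column names used in the file; identity for canonical names
        not listed.

    Returns
    -------
    ReadResult
        ``data`` holds one record per valid row; ``rejected`` carries
        rows violating the record invariants, with a ``reason`` column.

    Raises
    ------
    SumstatsFormatError
        If a mapped column is absent from the file.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    column_map = dict(column_map or {})
    src_names = {canon: column_map.get(canon, canon) for canon in COLUMNS}
    missing = [src for src in src_names.values() if src not in raw.columns]
    if missing:
        raise SumstatsFormatError(
            f"missing column(s) {missing} in {path}; present: {list(raw.columns)}"
        )
    df = pd.DataFrame({canon: raw[src] for canon, src in src_names.items()})
    for col in ("pos", "eaf", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["ea"] = df["ea"].str.upper()
    df["oa"] = df["oa"].str.upper()
    data, rejected = validate_sumstats(df)
    data["pos"] = data["pos"].astype(int)
    data["n"] = data["n"].astype(int)
    return ReadResult(data, rejected)


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write records in the canonical TSV dialect."""
    df.loc[:, COLUMNS].to_csv(path, sep="\t", index=False)


def _check_unique(df: pd.DataFrame, label: str) -> None:
    dup = df["snp"][df["snp"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate snp_id in {label} input: {sorted(set(dup))}")


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindrome_eaf_band: float = 0.08,
) -> HarmonizeResult:
    """Align outcome records to the exposure effect allele, SNP by SNP.

    Only SNPs present in both inputs are considered.  For each shared SNP:

    * identical effect/other alleles -> kept as is;
    * swapped alleles -> the outcome beta is negated and its EAF replaced
      by 1 - EAF (``outcome_flipped``);
    * a strand complement (e.g. A/G vs T/C) is reconciled before any
      mismatch verdict and recorded in the audit (``strand_flip``);
    * palindromic SNPs (A/T, C/G) with EAF within 0.5 +/- band on either
      trait are dropped as strand-ambiguous; outside the band they are
      aligned by frequency agreement (a band of 0.5 drops all palindromes);
    * anything else is dropped as an allele mismatch.

    Returns the kept, aligned pairs and an audit table listing the action
    taken for every shared SNP.
    """
    _check_unique(exposure, "exposure")
    _check_unique(outcome, "outcome")
    merged = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))

    rows = []
    audit = []
    for rec in merged.itertuples(index=False):
        ea_e, oa_e = rec.ea_exp, rec.oa_exp
        ea_o, oa_o = rec.ea_out, rec.oa_out
        beta_out, eaf_out = rec.beta_out, rec.eaf_out
        action = None
        strand_flip = False

        if is_palindromic(ea_e, oa_e):
            ambiguous = (
                abs(rec.eaf_exp - 0.5) <= palindrome_eaf_band
                or abs(eaf_out - 0.5) <= palindrome_eaf_band
            )
            if ambiguous or {ea_o, oa_o} != {ea_e, oa_e}:
                action = (
                    DROPPED_PALINDROMIC if ambiguous else DROPPED_MISMATCH
                )
            elif (rec.eaf_exp < 0.5) == (eaf_out < 0.5):
                action = KEPT
            else:
                action = FLIPPED
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
        else:
            if (ea_o, oa_o) == (ea_e, oa_e):
                action = KEPT
            elif (ea_o, oa_o) == (oa_e, ea_e):
                action = FLIPPED
            else:
                comp = (_COMPLEMENT[ea_o], _COMPLEMENT[oa_o])
                if comp == (ea_e, oa_e):
                    action, strand_flip = KEPT, True
                elif comp == (oa_e, ea_e):
                    action, strand_flip = FLIPPED, True
                else:
                    action = DROPPED_MISMATCH
            if action == FLIPPED:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out

        audit.append(
            {"snp": rec.snp, "action": action, "strand_flip": strand_flip}
        )
        if action in (KEPT, FLIPPED):
            rows.append(
                {
                    "snp": rec.snp,
                    "chr": rec.chr_exp,
                    "pos": rec.pos_exp,
                    "ea": ea_e,
                    "oa": oa_e,
                    "eaf_exp": rec.eaf_exp,
                    "beta_exp": rec.beta_exp,
                    "se_exp": rec.se_exp,
                    "p_exp": rec.p_exp,
                    "n_exp": rec.n_exp,
                    "eaf_out": eaf_out,
                    "beta_out": beta_out,
                    "se_out": rec.se_out,
                    "p_out": rec.p_out,
                    "n_out": rec.n_out,
                    "action": action,
                }
            )

    pair_cols = [
        "snp", "chr", "pos", "ea", "oa",
        "eaf_exp", "beta_exp", "se_exp", "p_exp", "n_exp",
        "eaf_out", "beta_out", "se_out", "p_out", "n_out", "action",
    ]
    pairs = pd.DataFrame(rows, columns=pair_cols)
    audit_df = pd.DataFrame(audit, columns=["snp", "action", "strand_flip"])
    return HarmonizeResult(pairs, audit_df)


def pairs_to_sumstats(pairs: pd.DataFrame, side: str) -> pd.DataFrame:
    """Project one side (``exp`` or ``out``) of a harmonized pair table
    back into the canonical single-trait dialect."""
    out = pd.DataFrame(
        {
            "snp": pairs["snp"],
            "chr": pairs["chr"],
            "pos": pairs["pos"],
            "ea": pairs["ea"],
            "oa": pairs["oa"],
            "eaf": pairs[f"eaf_{side}"],
            "beta": pairs[f"beta_{side}"],
            "se": pairs[f"se_{side}"],
            "p": pairs[f"p_{side}"],
            "n": pairs[f"n_{side}"],
        }
    )
    return out
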