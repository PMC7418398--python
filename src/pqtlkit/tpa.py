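"""Label-free absolute protein quantification (total protein approach).

A protein's concentration is its share of total MS2 signal divided by its
molecular mass:

    concentration_i [pmol/mg] = signal_i / (total_signal * mass_i) * 1e9

Signals of peptides shared between proteins are first redistributed to
the carriers in proportion to their unique-peptide totals.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import PeptideSignalTable, ProteinMatrix
from .errors import DomainError, InputValidationError

logger = logging.getLogger(__name__)


def sum_unique_signals(table: PeptideSignalTable, sample: str) -> dict[str, float]:
    """Per-protein totals of unique-peptide MS2 areas for one sample.

    Proteins that appear only in shared groups get 0.  Peptides without a
    detected area (NaN) contribute nothing.
    """
    areas = table.table[sample].to_numpy(dtype=float)
    if np.nanmin(areas, initial=0.0) < 0:
        raise InputValidationError("negative MS2 peak area")
    totals: dict[str, float] = {p: 0.0 for p in table.proteins}
    unique = table.is_unique()
    for idx, group in enumerate(table.table["protein_ids"]):
        if unique[idx] and np.isfinite(areas[idx]):
            totals[group[0]] += float(areas[idx])
    return totals


@dataclass
class RedistributionResult:
    """Per-protein MS2 signal after shared-peptide redistribution."""

    signal: dict[str, float]
    #: shared area that could not be assigned (all carriers had zero
    #: unique signal), per peptide id
    unassignable: dict[str, float] = field(default_factory=dict)
    #: proteins detected only through unassignable shared peptides
    unquantifiable: set[str] = field(default_factory=set)


def redistribute_shared(table: PeptideSignalTable, sample: str) -> RedistributionResult:
    """Allocate each shared peptide's area to its carriers in proportion
    to their unique-signal totals.

    The split is applied peptide-wise: each shared peptide is divided by
    the unique totals of exactly its own carrier set.  Shared peptides
    whose carriers all have zero unique signal are flagged unassignable
    and excluded.
    """
    unique_totals = sum_unique_signals(table, sample)
    signal = dict(unique_totals)
    unassignable: dict[str, float] = {}
    touched: dict[str, bool] = {}

    areas = table.table[sample].to_numpy(dtype=float)
    unique = table.is_unique()
    for idx, group in enumerate(table.table["protein_ids"]):
        if unique[idx] or not np.isfinite(areas[idx]):
            continue
        denom = sum(unique_totals[p] for p in group)
        if denom <= 0.0:
            pid = table.table["peptide_id"].iat[idx]
            unassignable[pid] = float(areas[idx])
            for p in group:
                touched[p] = True
            continue
        for p in group:
            signal[p] += unique_totals[p] / denom * float(areas[idx])

    unquantifiable = {p for p in touched if unique_totals[p] == 0.0}
    if unassignable:
        logger.warning(
            "sample %s: %d shared peptide(s) unassignable (%.3g total area)",
            sample, len(unassignable), sum(unassignable.values()))
    return RedistributionResult(signal=signal, unassignable=unassignable,
                                unquantifiable=unquantifiable)


def tpa_concentration(ms2_signal_i: float, total_ms2: float, mass_i: float) -> float:
    """pmol of protein per mg total input protein."""
    if total_ms2 <= 0:
        raise DomainError("total MS2 signal must be > 0")
    if mass_i <= 0:
        raise DomainError("molecular mass must be > 0")
    return ms2_signal_i / (total_ms2 * mass_i) * 1.0e9


def quantify_matrix(
    table: PeptideSignalTable,
    meta: pd.DataFrame,
    total_signal: str = "all",
    quantify: list[str] | None = None,
) -> ProteinMatrix:
    """Apply redistribution + TPA per sample to build the concentration
    matrix.

    Parameters
    ----------
    meta : DataFrame
        Protein metadata with at least ``protein`` and ``mass`` columns;
        every protein appearing in the table must be present.
    total_signal : {"all", "quantified"}
        Denominator convention: all reported peptide areas (default,
        includes peptides of proteins that are not themselves quantified)
        or only areas assigned to quantified proteins.
    quantify : list of protein IDs, optional
        Restrict the output rows; defaults to all proteins in the table.

    Proteins with no detected peptide in a sample are missing (NaN), not
    zero.
    """
    if total_signal not in ("all", "quantified"):
        raise InputValidationError("total_signal must be 'all' or 'quantified'")
    known = set(meta["protein"])
    unknown = sorted(set(table.proteins) - known)
    if unknown:
        raise InputValidationError(f"proteins missing from metadata: {unknown}")

    proteins = list(table.proteins) if quantify is None else list(quantify)
    mass = meta.set_index("protein")["mass"]
    out = np.full((len(proteins), len(table.samples)), np.nan)

    # a protein is quantified in a sample iff it has unique-peptide
    # evidence there; shared-only detections stay missing
    detected = {p: np.zeros(len(table.samples), dtype=bool) for p in table.proteins}
    area_mat = table.table[table.samples].to_numpy(dtype=float)
    finite = np.isfinite(area_mat)
    unique_pep = table.is_unique()
    for idx, group in enumerate(table.table["protein_ids"]):
        if unique_pep[idx]:
            detected[group[0]] |= finite[idx]

    for j, sample in enumerate(table.samples):
        redis = redistribute_shared(table, sample)
        if total_signal == "all":
            total = float(np.nansum(area_mat[:, j]))
        else:
            total = float(sum(redis.signal.get(p, 0.0) for p in proteins))
        if total <= 0:
            continue  # empty sample: everything stays missing
        for i, p in enumerate(proteins):
            if not detected.get(p, np.zeros(1, bool))[j]:
                continue
            if p in redis.unquantifiable:
                continue
            out[i, j] = tpa_concentration(redis.signal.get(p, 0.0), total,
                                          float(mass[p]))

    values = pd.DataFrame(out, index=proteins, columns=table.samples)
    meta_out = meta[meta["protein"].isin(proteins)].reset_index(drop=True)
    return ProteinMatrix(values=values, meta=meta_out)
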