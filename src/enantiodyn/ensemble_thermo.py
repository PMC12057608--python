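"""Boltzmann-weighted aggregation of conformer ensembles.

Consumes tabulated conformer free energies (kcal/mol) and chiral-H chemical
shifts (ppm) of labelled complex classes and produces ensemble-averaged
quantities: the ensemble free energy, binding free energies
Delta_G_bind = G_complex - G_host - G_guest, the enantiodifference
DeltaDelta_G = Delta_G_bind(R-analyte) - Delta_G_bind(S-analyte), and the
shift difference Delta_delta = shift(R-analyte) - shift(S-analyte).  Under
this sign convention a positive DeltaDelta_G means the S-analyte binds more
strongly (heterochiral preference when the resolving agent is R).

Two aggregation modes are provided because reported ensemble energies in the
literature follow either convention: "weighted_mean" (Boltzmann-weighted
arithmetic mean of the conformer G_i) and "free_energy" (the ensemble free
energy -kT * ln sum_i exp(-G_i/kT)).  The mode is recorded in every summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import R as GAS_CONSTANT_J

from enantiodyn.core_io import ConformerRecord

__all__ = [
    "KB_KCAL_MOL_K",
    "EnsembleSummary",
    "boltzmann_weights",
    "aggregate",
    "delta_G_bind",
    "summarize",
    "enantio_differences",
]

#: molar gas constant in kcal/(mol K); kT at 298.15 K is 0.5925 kcal/mol
KB_KCAL_MOL_K = GAS_CONSTANT_J / 4184.0


@dataclass
class EnsembleSummary:
    """Aggregated quantities for one (analyte chirality, CRA chirality)
    complex class at temperature T."""

    ma_chirality: str
    cra_chirality: str
    T: float
    G_ensemble: float
    weighted_shift: float
    delta_G_bind: float | None = None
    mode: str = "weighted_mean"

    @property
    def pairing(self) -> str:
        return "homochiral" if self.ma_chirality == self.cra_chirality else "heterochiral"


def boltzmann_weights(records: list[ConformerRecord], T: float = 298.15) -> list[ConformerRecord]:
    """Return copies of the records with normalized Boltzmann weights
    w_i = exp(-(G_i - G_min)/kT) / sum_j exp(-(G_j - G_min)/kT).

    The G_min shift is for numerical stability only; weights are invariant to
    adding any constant to all G_i."""
    if not records:
        raise ValueError("empty ensemble")
    if T <= 0:
        raise ValueError("temperature must be positive")
    g = np.array([r.G for r in records], dtype=float)
    kt = KB_KCAL_MOL_K * T
    w = np.exp(-(g - g.min()) / kt)
    w /= w.sum()
    return [
        ConformerRecord(
            complex_class=r.complex_class, G=r.G, shift_chiral_H=r.shift_chiral_H,
            weight=float(wi),
        )
        for r, wi in zip(records, w)
    ]


def aggregate(
    records: list[ConformerRecord], T: float = 298.15, mode: str = "weighted_mean"
) -> tuple[float, float]:
    """(G_ensemble, weighted_shift) for one ensemble.

    mode "weighted_mean": G_ensemble = sum_i w_i G_i (lies in
    [min G_i, max G_i]); mode "free_energy":
    G_ensemble = -kT ln sum_i exp(-G_i/kT) (lies at or below min G_i).
    The shift is always the Boltzmann-weighted arithmetic mean."""
    weighted = boltzmann_weights(records, T=T)
    w = np.array([r.weight for r in weighted])
    g = np.array([r.G for r in weighted])
    shifts = np.array([r.shift_chiral_H for r in weighted])
    shift_avg = float(np.sum(w * shifts))
    if mode == "weighted_mean":
        g_ens = float(np.sum(w * g))
    elif mode == "free_energy":
        kt = KB_KCAL_MOL_K * T
        g_ens = float(g.min() - kt * np.log(np.sum(np.exp(-(g - g.min()) / kt))))
    else:
        raise ValueError("mode must be 'weighted_mean' or 'free_energy'")
    return g_ens, shift_avg


def delta_G_bind(G_complex: float, G_host: float, G_guest: float) -> float:
    """Binding free energy of the complex: G_complex - G_host - G_guest."""
    return G_complex - G_host - G_guest


def summarize(
    records: list[ConformerRecord],
    ma_chirality: str,
    cra_chirality: str,
    G_host: float | None = None,
    G_guest: float | None = None,
    T: float = 298.15,
    mode: str = "weighted_mean",
) -> EnsembleSummary:
    """Aggregate one complex class into an EnsembleSummary; binding free
    energy is filled in when host and guest reference energies are given."""
    g_ens, shift = aggregate(records, T=T, mode=mode)
    dg = (
        delta_G_bind(g_ens, G_host, G_guest)
        if G_host is not None and G_guest is not None
        else None
    )
    return EnsembleSummary(
        ma_chirality=ma_chirality,
        cra_chirality=cra_chirality,
        T=T,
        G_ensemble=g_ens,
        weighted_shift=shift,
        delta_G_bind=dg,
        mode=mode,
    )


def enantio_differences(
    summary_r_ma: EnsembleSummary, summary_s_ma: EnsembleSummary
) -> tuple[float, float]:
    """(DeltaDelta_G, Delta_delta) between the R-analyte and S-analyte complex
    classes sharing one resolving-agent chirality and temperature:
    DeltaDelta_G = Delta_G_bind(R) - Delta_G_bind(S) (kcal/mol),
    Delta_delta = shift(R) - shift(S) (ppm).  Antisymmetric under swapping the
    two inputs."""
    if summary_r_ma.cra_chirality != summary_s_ma.cra_chirality:
        raise ValueError("summaries must share the resolving-agent chirality")
    if abs(summary_r_ma.T - summary_s_ma.T) > 1e-9:
        raise ValueError("summaries must share the temperature")
    if summary_r_ma.ma_chirality != "R" or summary_s_ma.ma_chirality != "S":
        raise ValueError("pass the R-analyte summary first, the S-analyte second")
    if summary_r_ma.delta_G_bind is None or summary_s_ma.delta_G_bind is None:
        raise ValueError("both summaries need binding free energies")
    ddg = summary_r_ma.delta_G_bind - summary_s_ma.delta_G_bind
    ddelta = summary_r_ma.weighted_shift - summary_s_ma.weighted_shift
    return float(ddg), float(ddelta)
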