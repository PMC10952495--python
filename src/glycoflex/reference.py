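"""Published characterisation of horseradish peroxidase (HRP).

Reference thermodynamic and kinetic parameters for the plant (glycosylated,
pHRP) and recombinant (non-glycosylated, rHRP) forms of holo-HRP, as
determined experimentally for OPD turnover at 298 K and CD thermal melts at
222 nm. These serve as default ground truths for the synthetic generators
and as inputs for derived quantities (temperature optima, catalytic
efficiencies, stability differences).

Units: temperatures K; kcat s^-1; KM mM; ΔH‡ and ΔS‡ are the activation
enthalpy (kJ mol^-1) and entropy (kJ mol^-1 K^-1) at the reference
temperature T0 = 298 K; ΔCp‡ is the activation heat capacity
(kJ mol^-1 K^-1).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class HRPForm:
    """Measured parameters for one HRP form."""

    name: str
    tm_holo: float | None  # K, two-state melt midpoint of the holo form
    tm_apo: float | None  # K, of the apo form (None: no clear transition)
    kcat: float  # s^-1
    km: float  # mM
    dh_act: float  # kJ mol^-1, activation enthalpy at T0
    ds_act: float  # kJ mol^-1 K^-1, activation entropy at T0
    dcp_act: float  # kJ mol^-1 K^-1, activation heat capacity
    t0: float = 298.0  # K, reference temperature of the MMRT fit


#: Plant (glycosylated) horseradish peroxidase
PHRP = HRPForm(
    name="pHRP",
    tm_holo=350.8,
    tm_apo=310.3,
    kcat=917.0,
    km=0.92,
    dh_act=1.3,
    ds_act=1.13,
    dcp_act=-1.9,
)

#: Recombinant (non-glycosylated) horseradish peroxidase
RHRP = HRPForm(
    name="rHRP",
    tm_holo=342.0,
    tm_apo=None,
    kcat=86.2,
    km=0.98,
    dh_act=26.4,
    ds_act=1.18,
    dcp_act=-6.6,
)

#: N-linked glycosylation sites of HRP (asparagine residue numbers)
GLYCOSYLATION_SITES = (13, 57, 158, 186, 198, 214, 255, 268)

#: Molar extinction coefficient of the DAP product at 450 nm, M^-1 cm^-1
EPSILON_DAP_450 = 10600.0
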