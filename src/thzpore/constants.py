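"""Physical constants (CODATA) and derived per-bundle quantities."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants plus the ATP hydrolysis energy.

    ``Q_ATP`` is the hydrolysis energy of one ATP molecule, defaulting to
    10·k_B·T at the supplied temperature.  It is stored per molecule (J);
    the per-mole equivalent is ``Q_ATP * N_A``.
    """

    F: float = 96485.33212  # Faraday constant, C/mol
    R_u: float = 8.31446261815324  # gas constant, J/(mol K)
    k_B: float = 1.380649e-23  # Boltzmann constant, J/K
    N_A: float = 6.02214076e23  # Avogadro constant, 1/mol
    q_ele: float = 1.602176634e-19  # elementary charge, C
    Q_ATP: float = field(default=0.0)  # J per ATP molecule; 0 -> derive

    @staticmethod
    def at_temperature(T: float, Q_ATP: float | None = None) -> "PhysicalConstants":
        """Constants with Q_ATP = 10 k_B T unless explicitly overridden."""
        c = PhysicalConstants()
        q = 10.0 * c.k_B * T if Q_ATP is None else Q_ATP
        return PhysicalConstants(Q_ATP=q)

    def thermal_voltage(self, T: float) -> float:
        """R_u T / F in volts."""
        return self.R_u * T / self.F


CONSTANTS = PhysicalConstants.at_temperature(310.0)
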