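"""Independent high-accuracy integration of the swimming momentum balance.

Uses scipy's adaptive DOP853 on the same force law, so it checks only the
fixed-step integrator, not the model. Test helper; not part of the package.
"""

import numpy as np
from scipy.integrate import solve_ivp

from jellyswim.dynamics import SimulationConfig, _coefficient_arrays


def oracle_mean_speed(morph, pulse, env, cfg=None, rtol=1e-8):
    cfg = cfg or SimulationConfig()
    duration = cfg.n_periods * pulse.period

    def rhs(t, u):
        T, c, m_eff, w = _coefficient_arrays(
            np.array([float(t)]), morph, pulse, env, cfg.refill_thrust
        )
        return [(T[0] - c[0] * u[0] * abs(u[0]) - w) / m_eff[0]]

    sol = solve_ivp(
        rhs,
        (0.0, duration),
        [cfg.u0],
        method="DOP853",
        rtol=rtol,
        atol=1e-10,
        max_step=min(pulse.t_c, pulse.t_r) / 10.0,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    ts = np.arange(int(round(duration * cfg.output_rate)) + 1) / cfg.output_rate
    return float(np.mean(sol.sol(ts)[0]))
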