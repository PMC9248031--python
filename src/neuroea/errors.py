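"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (bounds, rates, file contents...)."""


class IntegrationError(RuntimeError):
    """Numerical blow-up during simulation.

    Carries ``t_fail`` (ms), the simulation time at which the membrane
    potential left the plausible range or became non-finite.
    """

    def __init__(self, t_fail: float, message: str | None = None):
        self.t_fail = float(t_fail)
        super().__init__(
            message or f"integration failure at t = {t_fail:.3f} ms"
        )
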