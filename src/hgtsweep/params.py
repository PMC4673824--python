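"""Parameter containers shared by the deterministic models.

All rates are per generation; one model time unit is one generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ParameterError(ValueError):
    """Raised when a parameter set violates its domain constraints."""


@dataclass(frozen=True)
class SweepParams:
    """Parameters of the two-compartment sweep model.

    Attributes
    ----------
    N : int
        Community carrying capacity (number of cells).
    s : float
        Selection coefficient, the fitness advantage of allele carriers
        (carrier fitness is ``1 + s``).  May be given directly or derived
        from ``b`` and ``eps`` as ``s = b - eps``.
    r : float
        Transfer-rate coefficient per gene per generation; a non-carrier
        acquires the allele with per-capita probability ``r * C``.
    m : float
        Migration rate: fraction of the community replaced per generation
        by allele-free immigrants.
    C0 : float
        Initial carrier fraction.
    b, eps : float, optional
        Local benefit of the trait and cost of carrying it.  If both are
        supplied they must satisfy ``s = b - eps``.
    """

    N: int
    s: float = None  # type: ignore[assignment]
    r: float = 0.0
    m: float = 0.0
    C0: float = 0.0
    b: float | None = field(default=None)
    eps: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.s is None:
            if self.b is None or self.eps is None:
                raise ParameterError("either s, or both b and eps, must be given")
            object.__setattr__(self, "s", self.b - self.eps)
        elif self.b is not None and self.eps is not None:
            if abs(self.s - (self.b - self.eps)) > 1e-12:
                raise ParameterError(
                    f"inconsistent selection coefficient: s={self.s} "
                    f"but b - eps = {self.b - self.eps}"
                )
        if self.N < 1:
            raise ParameterError(f"N must be >= 1, got {self.N}")
        if not 0.0 <= self.r <= 1.0:
            raise ParameterError(f"r must lie in [0, 1], got {self.r}")
        if not 0.0 <= self.m <= 1.0:
            raise ParameterError(f"m must lie in [0, 1], got {self.m}")
        if not 0.0 <= self.C0 <= 1.0:
            raise ParameterError(f"C0 must lie in [0, 1], got {self.C0}")
        if self.s < 0.0:
            raise ParameterError(
                f"s must be >= 0 (benefit exceeds carriage cost), got {self.s}"
            )


@dataclass(frozen=True)
class TwoPatchParams:
    """Parameters of the extended model with an explicit external environment.

    The focal patch follows ``focal`` (its ``m`` is ignored; migration is
    replaced by explicit exchange with the environment patch).  The
    environment has relative size ``env_size_ratio`` and its own selection
    coefficient ``s_env <= 0`` (the trait is disfavoured outside the focal
    patch).  ``exchange`` is the per-capita rate at which focal-patch cells
    swap with environment cells per generation.
    """

    focal: SweepParams
    env_size_ratio: float = 1.0
    s_env: float = 0.0
    exchange: float = 0.0
    C0_env: float = 0.0

    def __post_init__(self) -> None:
        if self.env_size_ratio < 0.0:
            raise ParameterError(
                f"env_size_ratio must be >= 0, got {self.env_size_ratio}"
            )
        if self.s_env > 0.0:
            raise ParameterError(
                f"s_env must be <= 0 (trait disfavoured outside), got {self.s_env}"
            )
        if self.s_env <= -1.0:
            raise ParameterError(
                f"s_env must exceed -1 (carrier fitness 1+s_env > 0), got {self.s_env}"
            )
        if not 0.0 <= self.exchange <= 1.0:
            raise ParameterError(f"exchange must lie in [0, 1], got {self.exchange}")
        if not 0.0 <= self.C0_env <= 1.0:
            raise ParameterError(f"C0_env must lie in [0, 1], got {self.C0_env}")
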