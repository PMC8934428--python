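"""Platform-independent energy estimation by operation counting.

Every classification is decomposed into arithmetic operations (AOs) and
memory accesses (MAs); total energy is

    E_tot = (N_load + N_store) * E_m + sum_x N_x * E_x

with per-operation energies for a 45 nm process (5 pJ per memory access,
0.9 pJ float add, 3.7 pJ float multiply, ...).  A multiply-accumulate (MAC)
counts as a single arithmetic operation with E_MAC = E_add + E_mult, and a
square root is costed as a division (same cycle count on a Cortex-M4F FPU).
Divisions by a constant are costed as multiplications (by the precomputed
reciprocal).  Microprocessor instruction overhead is deliberately excluded;
it surfaces only through the slope/offset of :func:`calibrate_hardware`.

Memory-access conventions (centralized here so the whole model shares them):

* every scalar operand fetched from a working array is one load; every scalar
  result written back is one store; register-resident accumulators and loop
  counters are free;
* a MAC therefore costs two loads (weight + input).  Exception: the LSTM
  gates process the concatenated input [x_t; h_{t-1}] cell by cell, so the
  per-cell input vector is loaded once per cell per step and only the weight
  is fetched per MAC;
* sigmoid/tanh are looked up in an interpolation table: 2 loads plus 4
  generic one-cycle float ops per evaluation; ReLU is one compare; log2 in
  the entropies is one one-cycle op plus one table load per call;
* an absolute value is one compare (sign test, negation folded);
* batch normalization is folded into the preceding convolution weights at
  inference and dropout is inactive, so neither contributes;
* the power spectrum is costed as a radix-2 real FFT: (N_w/2) * log2(N_w)
  butterflies at 4 multiplies + 6 adds + 6 loads + 4 stores each, plus the
  Hann window multiplies and the squared magnitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from .detectors import CnnArchitecture, RnnArchitecture, RfConfig
from .features import ENTROPY_BINS, BANDS_HZ, WindowSpec

__all__ = [
    "OperationCosts",
    "OpLedger",
    "EnergyReport",
    "CalibrationFit",
    "total_energy",
    "feature_op_counts",
    "rf_op_counts",
    "cnn_op_counts",
    "rnn_op_counts",
    "mac_count",
    "calibrate_hardware",
    "FEATURE_COMPONENTS",
]

# Activation look-up table cost (interpolated LUT).
LUT_LOADS = 2
LUT_OPS = 4  # generic one-cycle ops for the interpolation arithmetic
LOG_LUT_LOADS = 1
LOG_LUT_OPS = 1


@dataclass(frozen=True)
class OperationCosts:
    """Per-operation energies in pJ (45 nm process figures)."""

    memory: float = 5.0  # E_m, one load or store
    int32_add: float = 0.1
    int32_mult: float = 3.1
    float32_add: float = 0.9
    float32_mult: float = 3.7
    compare: float = 0.9
    float32_divide: float = 26.3
    one_cycle: float = 3.7  # generic one-cycle float op (LUT arithmetic, log2, floor)

    @property
    def mac(self) -> float:
        """E_MAC = E_add + E_mult."""
        return self.float32_add + self.float32_mult


#: Arithmetic-operation classes of the ledger (everything except load/store).
AO_CLASSES = (
    "int_add",
    "int_mult",
    "float_add",
    "float_mult",
    "compare",
    "float_div",
    "one_cycle",
    "mac",
)

_COST_OF = {
    "int_add": "int32_add",
    "int_mult": "int32_mult",
    "float_add": "float32_add",
    "float_mult": "float32_mult",
    "compare": "compare",
    "float_div": "float32_divide",
    "one_cycle": "one_cycle",
}


@dataclass
class OpLedger:
    """Operation counts for one component; ledgers add componentwise."""

    load: int = 0
    store: int = 0
    int_add: int = 0
    int_mult: int = 0
    float_add: int = 0
    float_mult: int = 0
    compare: int = 0
    float_div: int = 0
    one_cycle: int = 0
    mac: int = 0  # one MAC = one AO at E_add + E_mult

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v < 0 or int(v) != v:
                raise ValueError(f"count {f.name}={v} must be a non-negative integer")
            setattr(self, f.name, int(v))

    def __add__(self, other: "OpLedger") -> "OpLedger":
        return OpLedger(**{
            f.name: getattr(self, f.name) + getattr(other, f.name) for f in dc_fields(self)
        })

    def scaled(self, k: int) -> "OpLedger":
        return OpLedger(**{f.name: getattr(self, f.name) * k for f in dc_fields(self)})

    @property
    def memory_accesses(self) -> int:
        return self.load + self.store

    @property
    def arithmetic_ops(self) -> int:
        return sum(getattr(self, c) for c in AO_CLASSES)

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def total_energy(ledger: OpLedger, costs: OperationCosts | None = None) -> float:
    """E_tot in pJ for one ledger."""
    costs = costs or OperationCosts()
    e = ledger.memory_accesses * costs.memory
    for cls, attr in _COST_OF.items():
        e += getattr(ledger, cls) * getattr(costs, attr)
    e += ledger.mac * costs.mac
    return e


@dataclass
class EnergyReport:
    """Per-component ledgers with energy totals for one classification."""

    classifier: str
    components: list[tuple[str, OpLedger]] = field(default_factory=list)

    def add(self, name: str, ledger: OpLedger) -> None:
        self.components.append((name, ledger))

    def ledger(self, name: str) -> OpLedger:
        for n, l in self.components:
            if n == name:
                return l
        raise KeyError(name)

    @property
    def total(self) -> OpLedger:
        out = OpLedger()
        for _, l in self.components:
            out = out + l
        return out

    def component_energy_pj(self, costs: OperationCosts | None = None) -> dict[str, float]:
        costs = costs or OperationCosts()
        return {name: total_energy(l, costs) for name, l in self.components}

    def total_energy_pj(self, costs: OperationCosts | None = None) -> float:
        return total_energy(self.total, costs)

    def total_energy_uj(self, costs: OperationCosts | None = None) -> float:
        return self.total_energy_pj(costs) * 1e-6

    @property
    def arithmetic_ops(self) -> int:
        return self.total.arithmetic_ops

    @property
    def memory_accesses(self) -> int:
        return self.total.memory_accesses

    def to_dict(self, costs: OperationCosts | None = None) -> dict:
        costs = costs or OperationCosts()
        return {
            "classifier": self.classifier,
            "total_energy_uJ": self.total_energy_uj(costs),
            "arithmetic_ops": self.arithmetic_ops,
            "memory_accesses": self.memory_accesses,
            "components": [
                {
                    "name": name,
                    "energy_pJ": total_energy(l, costs),
                    "arithmetic_ops": l.arithmetic_ops,
                    "memory_accesses": l.memory_accesses,
                    "counts": l.as_dict(),
                }
                for name, l in self.components
            ],
        }

    def to_dataframe(self, costs: OperationCosts | None = None):
        import pandas as pd

        costs = costs or OperationCosts()
        return pd.DataFrame(
            [
                {
                    "component": name,
                    "energy_pJ": total_energy(l, costs),
                    "arithmetic_ops": l.arithmetic_ops,
                    "memory_accesses": l.memory_accesses,
                    **l.as_dict(),
                }
                for name, l in self.components
            ]
        )


# ---------------------------------------------------------------------------
# Feature-bank counting (per channel)
# ---------------------------------------------------------------------------

def _lut_activation(n: int) -> OpLedger:
    return OpLedger(load=LUT_LOADS * n, one_cycle=LUT_OPS * n)


def _band_bins(name: str, df: float) -> int:
    lo, hi = BANDS_HZ[name]
    return int(round(hi / df)) - int(round(lo / df)) + 1


def _feature_rules(spec: WindowSpec, n_bins: int = ENTROPY_BINS) -> dict[str, OpLedger]:
    """Per-channel operation counts for the 16 features and their shared
    intermediates, following the formulas of the feature bank."""
    n = spec.n_samples
    L = spec.n_bins
    df = spec.df
    n_butterfly = (n // 2) * int(math.log2(n))

    rules: dict[str, OpLedger] = {}
    # shared intermediates -------------------------------------------------
    rules["mean"] = OpLedger(load=n, float_add=n - 1, float_mult=1, store=1)
    rules["zero_mean"] = OpLedger(load=n, float_add=n, store=n)
    rules["squared"] = OpLedger(load=n, float_mult=n, store=n)
    rules["variance"] = OpLedger(load=n, float_add=n - 1, float_mult=1, store=1)
    rules["std"] = OpLedger(load=1, float_div=1, store=1)  # sqrt costed as divide
    rules["power_spectrum"] = (
        OpLedger(load=2 * n, float_mult=n, store=n)  # Hann window
        + OpLedger(load=6 * n_butterfly, store=4 * n_butterfly,
                   float_mult=4 * n_butterfly, float_add=6 * n_butterfly)
        + OpLedger(load=2 * L, float_mult=2 * L, float_add=L, store=L)  # |X|^2
    )
    # time-domain features -------------------------------------------------
    rules["maximum"] = OpLedger(load=n, compare=n - 1, store=1)
    rules["mad"] = OpLedger(load=n, compare=n, float_add=n - 1, float_mult=1, store=1)
    rules["skewness"] = OpLedger(load=2 * n + 2, float_mult=n + 2,
                                 float_add=n - 1, float_div=1, store=1)
    rules["kurtosis"] = OpLedger(load=n + 1, float_mult=n + 2,
                                 float_add=n - 1, float_div=1, store=1)
    rules["line_length"] = OpLedger(load=2 * (n - 1), float_add=(n - 1) + (n - 2),
                                    compare=n - 1, store=1)
    rules["entropy"] = (
        OpLedger(load=n, compare=n - 1, store=1)  # min scan
        + OpLedger(float_add=1, float_div=1)  # bin width reciprocal
        + OpLedger(load=2 * n, store=n, float_add=n, float_mult=n,
                   one_cycle=n, int_add=n)  # binning + counter updates
        + OpLedger(load=n_bins, float_mult=n_bins, store=n_bins)  # p_i
        + OpLedger(load=n_bins * (1 + LOG_LUT_LOADS), one_cycle=n_bins * LOG_LUT_OPS,
                   float_mult=n_bins, float_add=n_bins - 1, store=1)
    )
    # frequency-domain features -------------------------------------------
    rules["spectral_entropy"] = (
        OpLedger(load=L, float_add=L - 1)  # total power
        + OpLedger(float_div=1)
        + OpLedger(load=L, float_mult=L, store=L)  # p_i
        + OpLedger(load=L * (1 + LOG_LUT_LOADS), one_cycle=L * LOG_LUT_OPS,
                   float_mult=L, float_add=L - 1, store=1)
    )
    rules["mean_spectral_power"] = OpLedger(load=L, float_add=L - 1, float_mult=1, store=1)
    rules["max_spectral_power"] = OpLedger(load=L, compare=L - 1, store=1)
    rules["spectral_power_variance"] = OpLedger(load=L, float_add=2 * L - 1,
                                                float_mult=L + 1, store=1)
    for band in ("theta", "alpha", "beta", "gamma"):
        nb = _band_bins(band, df)
        rules[f"{band}_power"] = OpLedger(load=nb, float_add=nb - 1, store=1)
    rules["epileptogenicity_index"] = OpLedger(load=4, float_add=2, float_div=1, store=1)
    return rules


#: Component names of the RF feature stage, in evaluation order.
FEATURE_COMPONENTS = tuple(_feature_rules(WindowSpec()).keys())


def feature_op_counts(feature: str, spec: WindowSpec | None = None) -> OpLedger:
    """Per-channel ledger of one feature (or shared intermediate)."""
    spec = spec or WindowSpec()
    rules = _feature_rules(spec)
    if feature not in rules:
        raise KeyError(
            f"unknown feature {feature!r}; known: {', '.join(rules)}"
        )
    return rules[feature]


def rf_op_counts(
    rf: RfConfig | None = None,
    n_channels: int = 4,
    spec: WindowSpec | None = None,
) -> EnergyReport:
    """Worst-case RF classification: full feature bank x C channels plus 100
    trees developed to maximum depth."""
    rf = rf or RfConfig()
    spec = spec or WindowSpec()
    report = EnergyReport("rf")
    for name, ledger in _feature_rules(spec).items():
        report.add(name, ledger.scaled(n_channels))
    nodes = rf.n_trees * rf.max_depth
    report.add(
        "tree_traversal",
        OpLedger(load=2 * nodes, compare=nodes, store=rf.n_trees),
    )
    report.add(
        "vote_aggregation",
        OpLedger(load=rf.n_trees, float_add=rf.n_trees, compare=1, store=1),
    )
    return report


# ---------------------------------------------------------------------------
# CNN / RNN counting
# ---------------------------------------------------------------------------

def _dot_outputs(n_outputs: int, k: int, relu: bool, input_reuse: int = 1) -> OpLedger:
    """``n_outputs`` dot products of length ``k`` with bias and activation.

    ``input_reuse``: number of dot products sharing one fetch of the input
    vector (1 = every MAC loads its own operand pair).
    """
    macs = n_outputs * k
    input_loads = macs if input_reuse == 1 else (n_outputs // input_reuse) * k
    ledger = OpLedger(
        mac=macs,
        load=macs + input_loads + n_outputs,  # weights + inputs + biases
        float_add=n_outputs,  # bias adds
        store=n_outputs,
    )
    if relu:
        ledger = ledger + OpLedger(compare=n_outputs)
    return ledger


def cnn_op_counts(arch: CnnArchitecture | None = None, n_channels: int = 4) -> EnergyReport:
    """Per-layer inference ledger of the CNN (batch norm folded, dropout off)."""
    arch = arch or CnnArchitecture()
    report_arch = arch.describe(n_channels)
    report = EnergyReport("cnn")

    n_in = n_channels * arch.n_input_samples
    report.add(
        "input_normalization",
        OpLedger(load=n_in, float_mult=n_in, store=n_in) + _lut_activation(n_in),
    )

    maps_in, height = 1, n_channels
    t = arch.n_input_samples
    for i, (f_out, k) in enumerate(zip(arch.conv_filters, arch.conv_kernels)):
        t_out = t - k + 1
        kernel = height * maps_in * k
        report.add(f"conv{i + 1}", _dot_outputs(t_out * f_out, kernel, relu=True))
        report.add(f"batchnorm{i + 1}_folded", OpLedger())
        height, maps_in, t = 1, f_out, t_out
        if i < len(arch.pool_sizes):
            p = arch.pool_sizes[i]
            t_p = t // p
            report.add(
                f"maxpool{i + 1}",
                OpLedger(load=t_p * f_out * p, compare=t_p * f_out * (p - 1),
                         store=t_p * f_out),
            )
            t = t_p
    n_flat = t * maps_in
    for i, units in enumerate(arch.dense_units):
        report.add(f"dense{i + 1}", _dot_outputs(units, n_flat, relu=True))
        n_flat = units
    report.add("output", _dot_outputs(1, n_flat, relu=False) + _lut_activation(1))

    # sanity: the shape chain used here must match the architecture report
    assert report_arch.shape_of("output") == (1,)
    return report


def rnn_op_counts(arch: RnnArchitecture | None = None, n_channels: int = 4) -> EnergyReport:
    """Per-layer inference ledger of the LSTM network over all time steps."""
    arch = arch or RnnArchitecture()
    c, h, t = n_channels, arch.lstm_units, arch.n_input_samples
    report = EnergyReport("rnn")

    n_d = (t - 1) * c
    report.add("time_derivative", OpLedger(load=2 * n_d, float_add=n_d, store=n_d))

    # LSTM step: 4 gates of h units, each a dot product over (c + h) inputs.
    # The concatenated input vector is fetched once per cell and shared by the
    # cell's four gates; weights are fetched per MAC.
    k = c + h
    gate_macs = 4 * h * k
    step = OpLedger(
        mac=gate_macs,
        load=gate_macs + h * k + 4 * h,  # weights + per-cell inputs + biases
        float_add=4 * h,  # bias adds
        store=4 * h,  # gate pre-activations
    )
    step = step + _lut_activation(5 * h)  # i, f, g, o and tanh(c)
    step = step + OpLedger(  # c = f*c + i*g ; h = o*tanh(c)
        float_mult=3 * h,
        float_add=h,
        load=6 * h,
        store=2 * h,  # new cell state and hidden state
    )
    report.add("lstm", step.scaled(t))

    report.add("td_dense", _dot_outputs(arch.td_units, h, relu=False).scaled(t))
    report.add(
        "global_average_pooling",
        OpLedger(load=t * arch.td_units, float_add=(t - 1) * arch.td_units,
                 float_mult=arch.td_units, store=arch.td_units),
    )
    report.add("output", _dot_outputs(1, arch.td_units, relu=False) + _lut_activation(1))
    return report


def mac_count(report: EnergyReport, stages: list[str] | None = None) -> int:
    """Total MAC operations over the selected components (all when None)."""
    total = 0
    names = {n for n, _ in report.components}
    if stages is not None:
        unknown = set(stages) - names
        if unknown:
            raise KeyError(f"unknown stages: {sorted(unknown)}")
    for name, ledger in report.components:
        if stages is None or name in stages:
            total += ledger.mac
    return total


# ---------------------------------------------------------------------------
# Hardware calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationFit:
    """OLS fit of measured vs. estimated energy: measured = b0 + b1 * estimate."""

    slope: float  # b1, hardware-dependent scale (instruction overhead)
    offset: float  # b0, uJ, static power of the target system
    adj_r_squared: float
    pearson_r: float
    slope_stderr: float
    offset_stderr: float


def calibrate_hardware(estimates, measurements) -> CalibrationFit:
    """Linear OLS regression of hardware measurements on model estimates (uJ)."""
    import statsmodels.api as sm
    from scipy import stats

    x = np.asarray(estimates, dtype=float)
    y = np.asarray(measurements, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("estimates and measurements must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a meaningful fit")
    if np.var(x) == 0:
        raise ValueError("estimates have zero variance; slope is unidentifiable")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r = float(stats.pearsonr(x, y).statistic)
    return CalibrationFit(
        slope=float(model.params[1]),
        offset=float(model.params[0]),
        adj_r_squared=float(model.rsquared_adj),
        pearson_r=r,
        slope_stderr=float(model.bse[1]),
        offset_stderr=float(model.bse[0]),
    )
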