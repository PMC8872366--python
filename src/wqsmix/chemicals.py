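"""Chemical panel definitions for the 26-component endocrine-disruptor mixture.

The default panel mirrors a Swedish pregnancy-cohort biomonitoring study:
26 chemicals in five classes — phenols and plasticizer/short-lived
metabolites measured in urine (creatinine-adjusted), PFAS in serum, and
persistent chlorinated compounds in plasma.  Summed variables (DEHP, DINP,
DDT+DDE, the PCB sum) enter as single components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CLASS_PHENOL = "phenol"
CLASS_PLASTICIZER = "plasticizer"
CLASS_SHORT_LIVED = "short_lived"
CLASS_PFAS = "pfas"
CLASS_PERSISTENT_CHLORINATED = "persistent_chlorinated"

CHEMICAL_CLASSES = (
    CLASS_PHENOL,
    CLASS_PLASTICIZER,
    CLASS_SHORT_LIVED,
    CLASS_PFAS,
    CLASS_PERSISTENT_CHLORINATED,
)

#: classes with long environmental/biological half-lives; the complement is
#: "non-persistent" in the exposure-reduction scenarios
PERSISTENT_CLASSES = frozenset({CLASS_PFAS, CLASS_PERSISTENT_CHLORINATED})


@dataclass(frozen=True)
class ChemicalSpec:
    """One mixture component: identity plus lognormal marginal parameters.

    Parameters
    ----------
    name : str
        Chemical (or summed-variable) label.
    chem_class : str
        One of :data:`CHEMICAL_CLASSES`.
    log_mean, log_sd : float
        Location and scale of the log-concentration marginal used by the
        synthetic cohort generator.
    detect_rate : float
        Fraction of samples expected above the limit of detection, in [0, 1].
    urinary : bool
        True for analytes measured in urine (subject to creatinine
        adjustment); False for serum/plasma analytes.
    """

    name: str
    chem_class: str
    log_mean: float = 0.0
    log_sd: float = 1.0
    detect_rate: float = 1.0
    urinary: bool = field(default=True)

    def __post_init__(self) -> None:
        if self.chem_class not in CHEMICAL_CLASSES:
            raise ValueError(
                f"unknown chemical class {self.chem_class!r} for {self.name!r}; "
                f"expected one of {CHEMICAL_CLASSES}"
            )
        if not 0.0 <= self.detect_rate <= 1.0:
            raise ValueError(
                f"detect_rate for {self.name!r} must be in [0, 1], got {self.detect_rate}"
            )
        if self.log_sd <= 0:
            raise ValueError(f"log_sd for {self.name!r} must be positive")


def _spec(name, chem_class, log_mean, log_sd=0.9, detect_rate=0.99, urinary=True):
    return ChemicalSpec(name, chem_class, log_mean, log_sd, detect_rate, urinary)


def default_chemicals() -> list[ChemicalSpec]:
    """The default 26-chemical panel, partitioned 4/9/3/6/4 across classes.

    Marginal parameters are plausible round numbers for biomonitoring data
    (lognormal concentrations, detection rates near 100%); they are generator
    defaults, not cohort-specific estimates.
    """
    phenols = [
        _spec("Triclosan", CLASS_PHENOL, 0.0, 1.4, 0.95),
        _spec("BPA", CLASS_PHENOL, 0.5, 0.8, 0.99),
        _spec("BPF", CLASS_PHENOL, -0.7, 1.1, 0.90),
        _spec("BPS", CLASS_PHENOL, -1.2, 1.0, 0.88),
    ]
    plasticizers = [
        _spec("MEP", CLASS_PLASTICIZER, 3.2, 1.2),
        _spec("MBP", CLASS_PLASTICIZER, 3.6, 0.7),
        _spec("MBzP", CLASS_PLASTICIZER, 2.1, 1.0),
        _spec("DEHP", CLASS_PLASTICIZER, 4.0, 0.6),
        _spec("DINP", CLASS_PLASTICIZER, 3.4, 0.8),
        _spec("MHiDP", CLASS_PLASTICIZER, 0.8, 0.8),
        _spec("MCiNP", CLASS_PLASTICIZER, 0.4, 0.7),
        _spec("MOiNCH", CLASS_PLASTICIZER, -0.9, 1.0, 0.92),
        _spec("DPHP", CLASS_PLASTICIZER, -0.3, 0.8, 0.96),
    ]
    short_lived = [
        _spec("TCP", CLASS_SHORT_LIVED, 0.3, 0.9),
        _spec("PBA", CLASS_SHORT_LIVED, -0.2, 1.1, 0.94),
        _spec("2OHPH", CLASS_SHORT_LIVED, -1.0, 0.7),
    ]
    pfas = [
        _spec("PFOA", CLASS_PFAS, 0.6, 0.5, 1.0, urinary=False),
        _spec("PFOS", CLASS_PFAS, 1.6, 0.5, 1.0, urinary=False),
        _spec("PFNA", CLASS_PFAS, -0.5, 0.5, 1.0, urinary=False),
        _spec("PFDA", CLASS_PFAS, -1.2, 0.5, 0.99, urinary=False),
        _spec("PFUnDA", CLASS_PFAS, -1.5, 0.6, 0.98, urinary=False),
        _spec("PFHxS", CLASS_PFAS, 0.2, 0.7, 1.0, urinary=False),
    ]
    chlorinated = [
        _spec("HCB", CLASS_PERSISTENT_CHLORINATED, 2.9, 0.4, 1.0, urinary=False),
        _spec("Nonachlor", CLASS_PERSISTENT_CHLORINATED, 1.2, 0.6, 0.99, urinary=False),
        _spec("DDT_DDE", CLASS_PERSISTENT_CHLORINATED, 3.6, 0.9, 1.0, urinary=False),
        _spec("PCB_sum", CLASS_PERSISTENT_CHLORINATED, 4.3, 0.5, 1.0, urinary=False),
    ]
    return phenols + plasticizers + short_lived + pfas + chlorinated


def class_map(chems: list[ChemicalSpec]) -> dict[str, str]:
    """Mapping from chemical name to chemical class."""
    return {c.name: c.chem_class for c in chems}
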