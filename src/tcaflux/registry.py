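"""Metabolite registry: carbon counts and MRM transitions.

The MRM (multiple-reaction-monitoring) precursor/product m/z pairs are the
negative-mode transitions used to quantify the unlabeled TCA intermediates
by LC-MS/MS; they label the acquisition channel for each metabolite.
Mass shifts of labeled isotopologues add 1 m/z per heavy carbon to the
precursor ion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError


@dataclass(frozen=True)
class MetaboliteInfo:
    name: str
    n_carbons: int
    mrm_precursor_mz: float | None = None
    mrm_product_mz: float | None = None

    @property
    def mrm_transition(self) -> str | None:
        if self.mrm_precursor_mz is None:
            return None
        return f"{self.mrm_precursor_mz:g}/{self.mrm_product_mz:g}"


#: Carbon skeletons of the pools tracked by the simulator plus the MRM
#: transitions of the intermediates measured on the QTRAP.
METABOLITES: dict[str, MetaboliteInfo] = {
    m.name: m
    for m in [
        MetaboliteInfo("citrate", 6, 191, 173),
        MetaboliteInfo("glutamate", 5, 146, 128),
        MetaboliteInfo("malate", 4, 133, 115),
        MetaboliteInfo("succinate", 4, 117, 99),
        MetaboliteInfo("pyruvate", 3),
        MetaboliteInfo("alpha_ketoglutarate", 5),
        MetaboliteInfo("oxaloacetate", 4),
        MetaboliteInfo("acetyl_coa", 2),
        MetaboliteInfo("glucose", 6),
        MetaboliteInfo("glutamine", 5),
        MetaboliteInfo("palmitate", 16),
        MetaboliteInfo("lactate", 3),
    ]
}


def metabolite_info(name: str) -> MetaboliteInfo:
    """Look up a metabolite by (case-insensitive) name."""
    key = name.strip().lower()
    if key not in METABOLITES:
        raise ConfigurationError(f"unknown metabolite: {name!r}")
    return METABOLITES[key]


def n_carbons(name: str) -> int:
    return metabolite_info(name).n_carbons
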