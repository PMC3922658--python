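"""Nearest-neighbor melting temperatures.

Thin wrapper over ``Bio.SeqUtils.MeltingTemp.Tm_NN`` exposing exactly the
knobs of :class:`~mirqpcr.config.ThermoConfig`.  The default configuration
(Sugimoto 1996 stacking parameters, Owczarzy 2008 sodium correction,
115 mM Na+, 40 nM primer over 20 nM template) is the calibration under which
the tail/trim sizing reproduces the reference primer set; see
docs/methods.md for how it was fixed.
"""

from __future__ import annotations

from Bio.SeqUtils import MeltingTemp as _mt

from .config import ThermoConfig

_TABLES = {
    "breslauer_1986": _mt.DNA_NN1,
    "sugimoto_1996": _mt.DNA_NN2,
    "santalucia_1997": _mt.DNA_NN3,
    "santalucia_2004": _mt.DNA_NN4,
}

_DNA = set("ACGT")


def melting_temperature(seq: str, config: ThermoConfig = ThermoConfig()) -> float:
    """Predicted duplex melting temperature of ``seq`` in Celsius.

    ``seq`` must be unambiguous DNA of length >= 2 (case-insensitive).
    The value is deterministic for a fixed configuration.
    """
    s = seq.upper()
    if len(s) < 2:
        raise ValueError("melting temperature needs at least 2 nt")
    bad = set(s) - _DNA
    if bad:
        raise ValueError(f"non-DNA character(s) {sorted(bad)} in sequence")
    return float(
        _mt.Tm_NN(
            s,
            nn_table=_TABLES[config.parameter_set],
            Na=config.sodium_mM,
            dnac1=config.oligo_nM,
            dnac2=config.template_nM,
            saltcorr=config.salt_correction,
        )
    )
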