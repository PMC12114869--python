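"""Frozen synthetic NIR band library (versioned fixture).

Per-analyte Gaussian absorption bands used by the spectra generator:
``(center_nm, width_nm, amplitude_per_mg_g)``.  The values are arbitrary but
fixed — they do not model real cannabinoid band assignments — and are kept in
this module so every run draws from the identical library.  Analytes with an
empty band list contribute nothing to the spectrum and act as unlearnable
negative controls for model validation.
"""

BAND_LIBRARY_VERSION = 1

#: analyte -> list of (center_nm, width_nm, amplitude per mg/g)
BAND_LIBRARY: dict[str, list[tuple[float, float, float]]] = {
    "CBDA":  [(1195.0, 28.0, 2.2e-3), (1448.0, 40.0, 1.6e-3), (1620.0, 30.0, 0.9e-3)],
    "THCA":  [(1212.0, 26.0, 2.0e-3), (1392.0, 36.0, 1.5e-3), (1538.0, 32.0, 1.0e-3)],
    "CBD":   [(1160.0, 24.0, 2.4e-3), (1502.0, 34.0, 1.4e-3)],
    "THC":   [(1240.0, 24.0, 2.3e-3), (1472.0, 30.0, 1.5e-3)],
    "CBC":   [(1122.0, 22.0, 1.8e-3), (1586.0, 28.0, 1.1e-3)],
    "CBN":   [(1302.0, 26.0, 2.1e-3), (1050.0, 30.0, 1.2e-3)],
    "CBDVA": [(1342.0, 28.0, 1.9e-3), (1570.0, 30.0, 1.0e-3)],
    "CBDV":  [(1088.0, 24.0, 1.7e-3)],
    "CBGA":  [(1268.0, 26.0, 1.9e-3), (1430.0, 34.0, 1.2e-3)],
    "CBG":   [(1022.0, 26.0, 1.6e-3)],
    "THCV":  [],   # zero-amplitude: unlearnable negative control
    "THCVA": [(1368.0, 26.0, 1.5e-3)],
    "CBNA":  [(1316.0, 24.0, 2.0e-3), (1604.0, 28.0, 1.1e-3)],
    "CBCA":  [(1146.0, 26.0, 1.4e-3)],
}
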