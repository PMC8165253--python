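"""Instrument and physical constants shared across the pipeline.

All quantities are SI (meters, seconds, pascals, Hz) unless the name says
otherwise.  Hemoglobin molar extinction coefficients are in cm^-1 / M and are
implementation constants taken from standard tabulations; the 800 nm pair is
forced equal so that 800 nm behaves as an exact isosbestic wavelength.
"""

#: Speed of sound used for water / soft tissue by default [m/s].
SOUND_SPEED_WATER = 1500.0

#: Planar raster-scan defaults: 128 x 128 points on a 100 um pitch at 10 Hz.
DEFAULT_NX = 128
DEFAULT_NY = 128
DEFAULT_PITCH = 100e-6
DEFAULT_REP_RATE = 10.0

#: Sensor defaults: -3 dB amplitude bandwidth and full-band noise floor.
DEFAULT_BANDWIDTH_3DB = 23e6
DEFAULT_NEP_PA = 65.8

#: Excitation pulse duration (FWHM) of the Ti:Sapphire / Nd:YAG source [s].
DEFAULT_PULSE_FWHM = 25e-9

#: Default time-sampling rate for simulated records [Hz].  The instrument's
#: digitizer rate is not modeled; this satisfies Nyquist at 23 MHz with margin.
DEFAULT_SAMPLING_RATE = 125e6

#: Molar extinction [cm^-1 / M] of oxy-/deoxyhemoglobin at the two imaging
#: wavelengths.  800 nm is treated as exactly isosbestic by construction.
HB_EXTINCTION = {
    800.0: {"HbO2": 816.0, "Hb": 816.0},
    1064.0: {"HbO2": 1062.0, "Hb": 204.0},
}

#: Typical oxygen saturation used for synthetic arteries and veins.
DEFAULT_SO2_ARTERY = 0.95
DEFAULT_SO2_VEIN = 0.65
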