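"""Compute RAU from stem assays and thermal time from daily weather.

The relative abundance of ureides (RAU) is the fraction of stem nitrogen
carried as ureides — the export form of symbiotically fixed N in soybean —
relative to ureides plus nitrate.  Thermal time above a base of 8 degC,
anchored at the V2 stage, is the developmental clock of the analysis.
"""

import datetime as dt

from bnfcurve import ThermalClock, WeatherRecord, compute_rau

# A stem assay: 120 umol ureide and 160 umol nitrate per g dry stem.
rau = compute_rau(120.0, 160.0)
print(f"RAU = {rau:.1f} %")
# 75.0 %: three quarters of stem N transport is ureide, a high-fixation crop.

# Ten warm days after V2 (29/19 degC -> mean 24, 16 degree-days each).
v2 = dt.date(2016, 6, 10)
weather = [WeatherRecord(v2 + dt.timedelta(days=i), 29.0, 19.0) for i in range(11)]
clock = ThermalClock(weather, origin_date=v2)
print(f"thermal time 10 days after V2 = {clock.at(v2 + dt.timedelta(days=10)):.0f} degCd")
# 160 degCd: the clock advances 16 degCd per day and reads 0 at V2 itself.
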