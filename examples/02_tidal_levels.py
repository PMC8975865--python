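"""Interpolate a site's mean tidal levels from nearby ports.

Three fictitious ports at 8, 15 and 28 km from the site contribute with
inverse-distance weights; levels are converted from Chart Datum to ODN
before averaging.
"""

from creekmorph.tides import PortRecord, interpolate_tidal_levels

ports = [
    PortRecord("Nearport", x=8_000, y=0,
               levels_cd=(9.8, 9.0, 7.2, 5.3, 3.1, 1.0), cd_to_odn=-4.9),
    PortRecord("Midport", x=0, y=15_000,
               levels_cd=(10.4, 9.6, 7.7, 5.6, 3.3, 1.2), cd_to_odn=-5.2),
    PortRecord("Farport", x=-28_000, y=0,
               levels_cd=(9.1, 8.3, 6.8, 5.0, 2.8, 0.8), cd_to_odn=-4.6),
]

levels = interpolate_tidal_levels((0.0, 0.0), ports)
for name in ("hat", "mhws", "mhwn", "mws", "mlwn", "mlws"):
    print(f"{name.upper():5s} = {getattr(levels, name):6.2f} m ODN")
# HAT is the crop level for the marsh extent; MWS anchors the mean marsh
# elevation parameter. Each level is a convex combination of the ports'.
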