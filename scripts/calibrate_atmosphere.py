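"""One-off calibration of the default atmospheric parameters.

The clear-sky model needs an ozone column, precipitable water, and
horizontal visibility, which are site conditions rather than model
constants.  This script fixes ozone (0.35 atm-cm, a mid-latitude summer
column) and precipitable water (4.0 cm, humid subtropical early summer)
and solves for the visibility that yields a June-15 solar-noon total
shortwave irradiance of 920.26 W/m^2 at the study-site latitude
(32.076 N).  The resulting values are frozen as the
``AtmosphericParams`` defaults; rerun only to recalibrate for a
different site.

Usage: python scripts/calibrate_atmosphere.py
"""

from scipy.optimize import brentq

from canopyflux.solar import AtmosphericParams, SiteTime, total_irradiance

TARGET_W_M2 = 920.26
LATITUDE = 32.076
DAY = 166  # June 15
OZONE_CM = 0.35
WATER_CM = 4.0
GROUND_ALBEDO = 0.2


def noon_total(visibility_km: float) -> float:
    atmos = AtmosphericParams(ozone_cm=OZONE_CM, water_cm=WATER_CM,
                              visibility_km=visibility_km,
                              ground_albedo=GROUND_ALBEDO)
    return total_irradiance(SiteTime(LATITUDE, DAY, 12.0), atmos).total


def main() -> None:
    vis = brentq(lambda v: noon_total(v) - TARGET_W_M2, 5.01, 40.0)
    vis_rounded = round(vis, 1)
    print(f"solved visibility_km = {vis:.4f} (frozen default: {vis_rounded})")
    print(f"noon total at frozen default: {noon_total(vis_rounded):.2f} W/m^2 "
          f"(target {TARGET_W_M2})")


if __name__ == "__main__":
    main()
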