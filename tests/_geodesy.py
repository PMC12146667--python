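"""Independent geodesic oracle: Vincenty inverse on the WGS84 ellipsoid."""

import numpy as np

A = 6378137.0
F = 1.0 / 298.257223563
B = A * (1.0 - F)


def vincenty_distance(lon1, lat1, lon2, lat2, tol=1e-12, maxiter=200):
    """Ellipsoidal geodesic distance in metres (Vincenty, 1975)."""
    if lon1 == lon2 and lat1 == lat2:
        return 0.0
    L = np.radians(lon2 - lon1)
    U1 = np.arctan((1 - F) * np.tan(np.radians(lat1)))
    U2 = np.arctan((1 - F) * np.tan(np.radians(lat2)))
    sinU1, cosU1 = np.sin(U1), np.cos(U1)
    sinU2, cosU2 = np.sin(U2), np.cos(U2)
    lam = L
    for _ in range(maxiter):
        sinlam, coslam = np.sin(lam), np.cos(lam)
        sin_sigma = np.sqrt(
            (cosU2 * sinlam) ** 2 + (cosU1 * sinU2 - sinU1 * cosU2 * coslam) ** 2
        )
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * coslam
        sigma = np.arctan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sinlam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sigma_m = (
            cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha if cos2_alpha > 0 else 0.0
        )
        C = F / 16.0 * cos2_alpha * (4.0 + F * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * F * sin_alpha * (
            sigma
            + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < tol:
            break
    u2 = cos2_alpha * (A**2 - B**2) / B**2
    k1 = (np.sqrt(1.0 + u2) - 1.0) / (np.sqrt(1.0 + u2) + 1.0)
    A_ = (1.0 + 0.25 * k1**2) / (1.0 - k1)
    B_ = k1 * (1.0 - 3.0 / 8.0 * k1**2)
    delta_sigma = B_ * sin_sigma * (
        cos_2sigma_m
        + B_ / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m**2)
            - B_ / 6.0 * cos_2sigma_m
            * (-3.0 + 4.0 * sin_sigma**2) * (-3.0 + 4.0 * cos_2sigma_m**2)
        )
    )
    return float(B * A_ * (sigma - delta_sigma))
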