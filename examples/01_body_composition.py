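"""Profile one player's body composition from raw skinfolds.

The four site means (mm) are summed; body density follows the schoolboy
log10 regression, percent fat the Siri conversion, and fat/fat-free mass
are normalized by squared height so that BMI = BFMI + FFMI.
"""

from weightgrade import aggregate_site, compose_profile

# three caliper replicates per site, in mm
skinfolds = {
    "biceps": [5.2, 5.3, 5.2],
    "triceps": [9.8, 9.9, 9.8],
    "subscapular": [7.1, 7.0, 7.1],
    "suprailiac": [10.4, 10.5, 10.4],
}
site_means = [aggregate_site(reps) for reps in skinfolds.values()]
profile = compose_profile(height=146.0, weight=41.5, site_means=site_means)

print(f"sum of 4 skinfolds : {profile.sum4:6.2f} mm")
print(f"body density       : {profile.body_density:6.4f} g/cm^3")
print(f"percent body fat   : {profile.percent_fat:6.2f} %")
print(f"fat mass           : {profile.fat_mass:6.2f} kg")
print(f"fat-free mass      : {profile.fat_free_mass:6.2f} kg")
print(f"BMI  = BFMI + FFMI : {profile.bmi:6.2f} = {profile.bfmi:.2f} + {profile.ffmi:.2f} kg/m^2")
# BFMI/FFMI place the player on the body-composition chart: this boy carries
# about a fifth of his BMI as fat, typical for a normal-weight schoolboy.
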