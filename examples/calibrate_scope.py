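"""Calibrate the camera and the focus lever arm against the stage.

The piezo stage is the length reference: stepping it laterally while
localizing a fiducial gives the pixel size; stepping it axially while
tracking the reflection spot gives the Z response (nm of defocus per px
of spot shift) and the direction the spot moves in.  Ground truth here is
80 nm/px and 40 nm/px, so the printed values show the recovery error.
"""

from stabilock import cmd_calibrate, default_config

res_px, res_z = cmd_calibrate(default_config(), seed=3)

print(f"pixel size : {res_px.pixel_size_nm:.3f} +/- {res_px.pixel_size_err:.3f} nm/px"
      f"   (r2 = {res_px.r2:.6f}; truth 80)")
print(f"z response : {res_z.z_response_nm_per_px:.3f} +/- {res_z.z_response_err:.3f} nm/px"
      f"   (r2 = {res_z.r2:.6f}; truth 40)")
print(f"z axis     : [{res_z.z_axis[0]:+.4f}, {res_z.z_axis[1]:+.4f}]  (truth [+1, 0])")
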