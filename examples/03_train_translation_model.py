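"""Train a small MRI->PET translation model on noiseless phantoms.

On noiseless phantoms the PET is a deterministic function of the T1w tissue
class, so even a narrow model learns the mapping quickly.  This runs a
deliberately short training (12 epochs, 4 pairs) and scores the held-out
prediction with masked MAE / PSNR / SSIM.  Expect SSIM around 0.77 here;
longer training (50 epochs) pushes SSIM above 0.9.
"""

import sipcom as sp


def make(seed):
    spec = sp.PhantomSpec(shape=(48, 48, 48), voxel_size_mm=2.0,
                          semi_axes_mm=(36, 40, 36),
                          noise_sd=0.0, smooth_fwhm_mm=0.0, seed=seed)
    return sp.generate_phantom(spec)


pairs = [(s.t1w, s.pet, s.mask) for s in map(make, range(4))]
held = make(10)

config = sp.GanConfig(
    enc_channels=(8, 16), dec_channels=(16, 8), disc_channels=(8, 16, 1),
    patch_edge=16, epochs=12, batch_size=8, patches_per_pair=16, seed=0,
)
state, history = sp.train_gan(pairs, config, progress=True)

pred = state.predict_volume(held.t1w, held.mask)
m = sp.evaluate_pair(pred, held.pet, held.mask)
print(f"\nheld-out masked MAE  {m.mae:.4f}")
print(f"held-out PSNR        {m.psnr:.2f} dB")
print(f"held-out masked SSIM {m.ssim:.4f}")
print(f"generator MSE fell from {history.g_mse.iloc[0]:.4f} "
      f"to {history.g_mse.iloc[-1]:.4f} over {len(history)} epochs")
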