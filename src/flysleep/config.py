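"""Session configuration for the synthetic-session generator.

Every spectral effect the downstream pipeline looks for is a tunable gain
here, expressed in dB relative to the stationary in-band noise floor.  The
defaults encode the study conditions the pipeline is designed to detect:
broadband (5-40 Hz) power higher in wake than sleep on every channel; a
central-channel (1-3) 5-10 Hz stage signature ordered
awake > presleep > earlysleep ~ latesleep > midsleep; a peripheral-channel
(12-16) 10-30 Hz day/night sleep difference; proboscis-extension (PE)
signatures that differ between wake (middle channels, broadband decrease)
and sleep (central channels, 32-40 Hz increase).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math


@dataclass
class PEBurstConfig:
    inter_pe_interval_mean: float = 1.5   # s between PEs within a burst
    inter_pe_interval_sd: float = 0.15
    p_single: float = 0.33                # fraction of bursts with one PE
    rate_midsleep_per_min: float = 0.5    # bursts per minute of midsleep
    rate_wake_per_min: float = 0.12
    rate_flank_per_min: float = 0.05      # early/late/presleep segments
    occlusion_fraction: float = 0.15      # PEs with a likelihood dip


@dataclass
class AntennaConfig:
    periodic_freq: float = 0.8            # Hz of rhythmic antennal motion
    periodic_fraction_sleep: float = 0.35
    periodic_fraction_wake: float = 0.10
    amplitude_deg: float = 8.0


@dataclass
class SessionConfig:
    n_channels: int = 16
    fs_lfp: float = 250.0                 # Hz (post-acquisition analysis rate)
    fps_video: float = 30.0
    duration: float = 3600.0              # s
    clock_start: float = 8 * 3600.0       # s since midnight at recording start
    reversal_channel: int = 11            # polarity-reversal channel, 1-based
    sleep_bout_rate: float = 2.0          # bouts per hour
    # lognormal(mu, sigma) bout durations in s; default median ~14 min (day)
    sleep_bout_duration: tuple[float, float] = (math.log(839.0), 0.5)
    night_duration_factor: float = 22.42 / 13.99  # night bouts longer
    wake_broadband_gain_db: float = 3.0
    # fraction of the broadband wake gain retained during presleep: the
    # brain is already part-way to sleep while the fly still moves, which
    # puts presleep between awake and earlysleep in classifier probability
    presleep_broadband_fraction: float = 0.33
    stage_profile: dict[str, float] = field(default_factory=lambda: {
        "awake": 0.0, "presleep": -1.0,
        "earlysleep": -2.0, "latesleep": -2.4, "midsleep": -5.0,
    })
    daynight_peripheral_delta_db: float = 2.0   # day sleep minus night sleep
    pe_wake_middle_delta_db: float = -2.5       # wake PEs, middle ch, 5-40 Hz
    pe_sleep_central_delta_db: float = 2.5      # sleep PEs, central ch, 32-40 Hz
    pe_burst: PEBurstConfig = field(default_factory=PEBurstConfig)
    antenna: AntennaConfig = field(default_factory=AntennaConfig)
    crepuscular_peaks: dict[str, float] = field(
        default_factory=lambda: {"dawn": 1.8, "dusk": 1.8})
    seed: int = 0
    frames_mode: str = "magnitude"        # 'magnitude' | 'frames'
    with_lfp: bool = True
    with_pose: bool = True

    def validate(self) -> None:
        if self.n_channels != 16:
            raise ValueError("n_channels: the linear probe has 16 sites")
        if self.fs_lfp <= 0:
            raise ValueError("fs_lfp must be positive")
        if self.fps_video <= 0:
            raise ValueError("fps_video must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not (1 <= self.reversal_channel <= 16):
            raise ValueError("reversal_channel must be in 1..16")
        if self.sleep_bout_rate < 0:
            raise ValueError("sleep_bout_rate must be non-negative")
        sp = self.stage_profile
        try:
            order_ok = (sp["awake"] > sp["presleep"]
                        > max(sp["earlysleep"], sp["latesleep"])
                        and min(sp["earlysleep"], sp["latesleep"]) > sp["midsleep"])
        except KeyError as e:
            raise ValueError(f"stage_profile missing stage {e}") from e
        if not order_ok:
            raise ValueError(
                "stage_profile must be ordered awake > presleep > "
                "earlysleep ~ latesleep > midsleep")
        for name in ("wake_broadband_gain_db", "daynight_peripheral_delta_db",
                     "pe_wake_middle_delta_db", "pe_sleep_central_delta_db"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not (0.0 <= self.pe_burst.p_single <= 1.0):
            raise ValueError("pe_burst.p_single must be in [0, 1]")
        if self.frames_mode not in ("magnitude", "frames"):
            raise ValueError("frames_mode must be 'magnitude' or 'frames'")
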