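# Default taxonomy and protocol configuration for a two-station raptor
# migration count.  Everything here is configuration, not code: pools,
# parent links, overlap geometry and windows can all be overridden from a
# user config file passed to load_protocol().

taxonomy:
  # child -> parent morphological group.  Species without an entry are
  # taxonomy roots (non-raptor singletons such as cranes and pelicans).
  parent:
    # buzzards / honey-buzzards
    HB: Pernis_SPEC
    CrestedHB: Pernis_SPEC
    StepBuz: Buzzard_SPEC
    CommonBuz: Buzzard_SPEC
    RoughLB: Buzzard_SPEC
    LongLB: Buzzard_SPEC
    Pernis_SPEC: Buzzard_SPEC
    Buzzard_SPEC: MediumRaptor
    # kites
    BlackKite: MediumRaptor
    RedKite: MediumRaptor
    MediumRaptor: Raptor_SPEC
    # large eagles
    LesserSE: LargeEAGLE
    GreaterSE: LargeEAGLE
    SteppeE: LargeEAGLE
    ImperialE: LargeEAGLE
    GoldenE: LargeEAGLE
    WhiteTE: LargeEAGLE
    LargeEAGLE: Raptor_SPEC
    # other raptors directly under the root group
    BootedE: Raptor_SPEC
    ShortTE: Raptor_SPEC
    Osprey: Raptor_SPEC
    EgyptianV: Raptor_SPEC
    GriffonV: Raptor_SPEC
    BlackV: Raptor_SPEC
    # harriers
    Mon: MonPalHen
    Pal: MonPalHen
    Hen: MonPalHen
    MonPalHen: Harrier_SPEC
    Mar: Harrier_SPEC
    Harrier_SPEC: Raptor_SPEC
    # sparrowhawks / goshawk
    LevantSH: SparrowH_SPEC
    EurasianSH: SparrowH_SPEC
    SparrowH_SPEC: SPH_Goshawk
    Goshawk: SPH_Goshawk
    SPH_Goshawk: Raptor_SPEC
    # falcons
    Hobby: Hobby_RedFF
    RedFF: Hobby_RedFF
    LesserKes: Kestrel_SPEC
    CommonKes: Kestrel_SPEC
    LannerF: LargeFALCON
    SakerF: LargeFALCON
    Peregrine: LargeFALCON
    EleonoraF: Falcon_SPEC
    Merlin: Falcon_SPEC
    Hobby_RedFF: Falcon_SPEC
    Kestrel_SPEC: Falcon_SPEC
    LargeFALCON: Falcon_SPEC
    Falcon_SPEC: Raptor_SPEC
    # storks (non-raptor group)
    WhiStork: Stork_SPEC
    BlaStork: Stork_SPEC

  # species with no group membership at all (counted but never pooled)
  ungrouped_species:
    - EurasianCrane
    - DemCrane
    - WhiteP
    - DalmatianP
    - Roller
    - TurtleD
    - WoodP
    - StockD

  # group -> species whose identified counts define allocation proportions
  pools:
    Pernis_SPEC: [HB, CrestedHB]
    Buzzard_SPEC: [HB, CrestedHB, StepBuz, CommonBuz, RoughLB, LongLB]
    MediumRaptor: [HB, CrestedHB, StepBuz, CommonBuz, RoughLB, LongLB,
                   BlackKite, RedKite]
    LargeEAGLE: [LesserSE, GreaterSE, SteppeE, ImperialE, GoldenE, WhiteTE]
    MonPalHen: [Mon, Pal, Hen]
    Harrier_SPEC: [Mar, Mon, Pal, Hen]
    SparrowH_SPEC: [LevantSH, EurasianSH]
    SPH_Goshawk: [LevantSH, EurasianSH, Goshawk]
    Hobby_RedFF: [Hobby, RedFF]
    Kestrel_SPEC: [LesserKes, CommonKes]
    LargeFALCON: [LannerF, SakerF, Peregrine]
    Falcon_SPEC: [Hobby, RedFF, LesserKes, CommonKes, LannerF, SakerF,
                  Peregrine, EleonoraF, Merlin]
    Raptor_SPEC: [HB, CrestedHB, StepBuz, CommonBuz, RoughLB, LongLB,
                  BlackKite, RedKite, LesserSE, GreaterSE, SteppeE, ImperialE,
                  GoldenE, WhiteTE, BootedE, ShortTE, Osprey, EgyptianV,
                  GriffonV, BlackV, Mar, Mon, Pal, Hen, LevantSH, EurasianSH,
                  Goshawk, Hobby, RedFF, LesserKes, CommonKes, LannerF,
                  SakerF, Peregrine, EleonoraF, Merlin]
    Stork_SPEC: [WhiStork, BlaStork]

  # monitoring status; species not listed have no monitoring status
  status:
    priority: [HB, BlackKite, LesserSE, BootedE, Mar, Mon, Pal]
    secondary: [StepBuz, GreaterSE, SteppeE, ImperialE, ShortTE, Osprey,
                Hen, EgyptianV, GriffonV, BlackV, LannerF, SakerF, Peregrine,
                WhiStork, BlaStork, EurasianCrane, DemCrane, WhiteP,
                DalmatianP, Roller, TurtleD, WoodP, StockD]

  # separate-age-protocol codes -> the species they sample
  age_protocol:
    HB_JUV: HB
    HB_NONJUV: HB
    BK_JUV: BlackKite
    BK_NONJUV: BlackKite
    SB_JUV: StepBuz
    SB_NONJUV: StepBuz

protocol:
  # small species: actively flapping migrants detectable only close by;
  # everything not listed is large (soaring species visible from afar)
  size_class:
    small: [Mar, Mon, Pal, Hen, MonPalHen, Harrier_SPEC,
            LevantSH, EurasianSH, Goshawk, SparrowH_SPEC, SPH_Goshawk,
            Hobby, RedFF, LesserKes, CommonKes, LannerF, SakerF, Peregrine,
            EleonoraF, Merlin, Hobby_RedFF, Kestrel_SPEC, LargeFALCON,
            Falcon_SPEC, Roller, TurtleD, WoodP, StockD]

  # double-count detection windows (minutes, +/- around the partner record)
  window_minutes:
    small: 10
    large: 15

  # distance-zone pairs (station 1 zone, station 2 zone) treated as the same
  # airspace; station 1 is the western, station 2 the eastern hilltop
  overlap_zones:
    small:
      - station1: [E2, E3, E4]
        station2: [W2, W3]
    large:
      - station1: [E1, E2, E3, E4]
        station2: [O, W1, W2, W3]
      - station1: [O]
        station2: [W3]

  # season window rule: start/end anchored to passage quantiles of the
  # earliest and latest priority species
  season_rules:
    start: {species: Mon, quantile: 0.01, offset_days: -3}
    end: {species: LesserSE, quantile: 0.99, offset_days: 3}

  # standardized daily count period (one hour after sunrise to two hours
  # before sunset, as fixed clock times) and the early-morning extension
  day_period:
    start: "07:00"
    end: "17:00"
    early_morning_start: "05:30"

  # what to do when a morphological group has a count but its pool has no
  # identified birds that day: season_proportions | skip | equal_split
  empty_pool_fallback: season_proportions

  # integer reporting convention
  rounding: half_up

  validation:
    # the latest-identified large eagle is identified on station even when
    # age is missing in the data, so it is not degraded by default
    degrade_lesser_spotted_without_age: false
    # flocks above this size for secondary species trigger a warning
    rare_flock_threshold: 5
    # species with a recorded-morph protocol and their allowed values
    morph_protocol:
      BootedE: [dark, light]
      Mar: [dark]
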