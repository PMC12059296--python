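{
  "_version": "1.0",
  "_comment": "Recommended occupancy factors for nuclear medicine departments (NCRP 147 convention). Keywords drive the lookup in get_occupancy.",
  "entries": [
    {
      "area": "Offices, labs, pharmacies, receptionist areas, attended waiting rooms, kids' play areas, imaging rooms, film reading areas, nursing stations, control rooms",
      "factor": 1.0,
      "keywords": ["office", "lab", "pharmacy", "receptionist", "attended waiting", "play area", "imaging room", "film reading", "nursing station", "control room"]
    },
    {
      "area": "Patient exam rooms, patient treatment rooms, nuclear medicine hot labs, PET uptake rooms",
      "factor": 0.5,
      "keywords": ["exam room", "treatment room", "hot lab", "uptake room", "uptake"]
    },
    {
      "area": "Corridors, patient rooms, employee lounges, staff rest rooms",
      "factor": 0.2,
      "keywords": ["corridor", "patient room", "lounge", "staff rest room", "hallway"]
    },
    {
      "area": "Corridor doors",
      "factor": 0.125,
      "keywords": ["corridor door", "door"]
    },
    {
      "area": "Public toilets, vending areas, storage rooms, outdoor areas with seating, unattended waiting rooms, patient holding",
      "factor": 0.05,
      "keywords": ["toilet", "vending", "storage", "outdoor seating", "unattended waiting", "patient holding", "holding"]
    },
    {
      "area": "Outdoors, unattended parking lots, attics, stairways, unattended elevators, janitor's closets",
      "factor": 0.025,
      "keywords": ["outdoor", "parking", "attic", "stairway", "stairs", "elevator", "janitor", "closet"]
    }
  ]
}
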