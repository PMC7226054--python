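{
  "first_names": ["Talissa", "Harlan", "Edwin", "Fay", "Quentin", "Marisol",
                  "Bertram", "Odette", "Caspian", "Lurleen", "Dexter", "Wilhelmina",
                  "Orson", "Perdita", "Thaddeus", "Zelda", "Ignatius", "Maribel"],
  "last_names": ["Oneil", "Foust", "Irish", "Quimby", "Vandermeer", "Ostrowski",
                 "Pemberton", "Lockhart", "Winterbourne", "Castellano", "Abernathy",
                 "Fairweather", "Mulligan", "Stroud", "Beaumont", "Kowalczyk"],
  "hospitals": ["Edwin HealthCare", "Mercy General Hospital", "Saint Olaf Hospital",
                "Lakeside Memorial Hospital", "Northfield Clinic",
                "Pinecrest Community Hospital", "Westbrook Medical Center"],
  "cities": ["Sulphur", "Newburgh", "Maplewood", "Crestfall", "Ambergris",
             "Dunmore", "Larkspur", "Veridian"],
  "states": ["Arkansas", "New Jersey", "Vermont", "Ohio", "New Hampshire",
             "Montana", "Rhode Island"],
  "streets": ["739 Newburgh Street", "12 Larkspur Lane", "480 Mill Road",
              "91 Harborview Drive", "27 Foxglove Circle", "308 Quarry Avenue"],
  "professions": ["carpenter", "teacher", "accountant", "florist", "machinist",
                  "librarian", "electrician", "pharmacist"],
  "countries": ["Freedonia", "Sylvania", "Arendelle", "Genovia", "Zubrowka"],
  "organizations": ["Acme Insurance", "Globex Mutual", "Initech Benefits",
                    "Vandelay Industries"]
}
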