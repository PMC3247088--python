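"""Bundled name and street lexicons for the synthetic-population generator.

Small common-name word lists, ordered roughly by familiarity so that a
rank-frequency (Zipf) sampler over them produces a plausible mix of very
common and rare names. Users with their own lexicons can pass them to
:class:`privrisk.syndata.NameModel` directly.
"""

FIRST_NAMES = [
    "james", "mary", "john", "patricia", "robert", "jennifer", "michael",
    "linda", "william", "elizabeth", "david", "barbara", "richard", "susan",
    "joseph", "jessica", "thomas", "sarah", "charles", "karen", "christopher",
    "nancy", "daniel", "lisa", "matthew", "margaret", "anthony", "betty",
    "mark", "sandra", "donald", "ashley", "steven", "dorothy", "paul",
    "kimberly", "andrew", "emily", "joshua", "donna", "kenneth", "michelle",
    "kevin", "carol", "brian", "amanda", "george", "melissa", "edward",
    "deborah", "ronald", "stephanie", "timothy", "rebecca", "jason", "laura",
    "jeffrey", "sharon", "ryan", "cynthia", "jacob", "kathleen", "gary",
    "amy", "nicholas", "shirley", "eric", "angela", "jonathan", "helen",
    "stephen", "anna", "larry", "brenda", "justin", "pamela", "scott",
    "nicole", "brandon", "emma", "benjamin", "samantha", "samuel",
    "katherine", "gregory", "christine", "frank", "debra", "alexander",
    "rachel", "raymond", "catherine", "patrick", "carolyn", "jack", "janet",
    "dennis", "ruth", "jerry", "maria", "tyler", "heather", "aaron", "diane",
    "jose", "virginia", "adam", "julie", "henry", "joyce", "nathan",
    "victoria", "douglas", "olivia", "zachary", "kelly", "peter", "christina",
    "kyle", "lauren", "walter", "joan", "ethan", "evelyn", "jeremy",
    "judith", "harold", "megan", "keith", "cheryl", "christian", "andrea",
    "roger", "hannah", "noah", "martha", "gerald", "jacqueline", "carl",
    "frances", "terry", "gloria", "sean", "ann", "austin", "teresa",
    "arthur", "kathryn", "lawrence", "sara", "jesse", "janice", "dylan",
    "jean", "bryan", "alice", "joe", "madison", "jordan", "doris", "billy",
    "abigail", "bruce", "julia", "albert", "judy", "willie", "grace",
    "gabriel", "denise", "logan", "amber", "alan", "marilyn", "juan",
    "beverly", "wayne", "danielle", "roy", "theresa", "ralph", "sophia",
    "randy", "marie", "eugene", "diana", "vincent", "brittany", "russell",
    "natalie", "elijah", "isabella", "louis", "charlotte", "bobby", "rose",
    "philip", "alexis", "johnny", "kayla", "bradley", "lillian", "curtis",
    "annie", "todd", "irene", "norman", "alma", "marvin", "vera", "glenn",
    "stella", "leroy", "wilma", "oscar", "gwendolyn", "dustin", "dolores",
    "pedro", "janie", "derrick", "lucille", "dana", "jeanne", "lonnie",
    "lorraine", "miguel", "sally", "felix", "regina", "cecil", "erica",
    "rufus", "beatrice", "abel", "dolly", "omar", "bernice", "horace",
    "audrey", "wendell", "yvonne", "ezra", "annette", "dewey", "june",
]

LAST_NAMES = [
    "smith", "johnson", "williams", "brown", "jones", "garcia", "miller",
    "davis", "rodriguez", "martinez", "hernandez", "lopez", "gonzalez",
    "wilson", "anderson", "thomas", "taylor", "moore", "jackson", "martin",
    "lee", "perez", "thompson", "white", "harris", "sanchez", "clark",
    "ramirez", "lewis", "robinson", "walker", "young", "allen", "king",
    "wright", "scott", "torres", "nguyen", "hill", "flores", "green",
    "adams", "nelson", "baker", "hall", "rivera", "campbell", "mitchell",
    "carter", "roberts", "gomez", "phillips", "evans", "turner", "diaz",
    "parker", "cruz", "edwards", "collins", "reyes", "stewart", "morris",
    "morales", "murphy", "cook", "rogers", "gutierrez", "ortiz", "morgan",
    "cooper", "peterson", "bailey", "reed", "kelly", "howard", "ramos",
    "kim", "cox", "ward", "richardson", "watson", "brooks", "chavez",
    "wood", "james", "bennett", "gray", "mendoza", "ruiz", "hughes",
    "price", "alvarez", "castillo", "sanders", "patel", "myers", "long",
    "ross", "foster", "jimenez", "powell", "jenkins", "perry", "russell",
    "sullivan", "bell", "coleman", "butler", "henderson", "barnes",
    "gonzales", "fisher", "vasquez", "simmons", "romero", "jordan",
    "patterson", "alexander", "hamilton", "graham", "reynolds", "griffin",
    "wallace", "moreno", "west", "cole", "hayes", "bryant", "herrera",
    "gibson", "ellis", "tran", "medina", "aguilar", "stevens", "murray",
    "ford", "castro", "marshall", "owens", "harrison", "fernandez",
    "mcdonald", "woods", "washington", "kennedy", "wells", "vargas",
    "henry", "chen", "freeman", "webb", "tucker", "guzman", "burns",
    "crawford", "olson", "simpson", "porter", "hunter", "gordon", "mendez",
    "silva", "shaw", "snyder", "mason", "dixon", "munoz", "hunt", "hicks",
    "holmes", "palmer", "wagner", "black", "robertson", "boyd", "rose",
    "stone", "salazar", "fox", "warren", "mills", "meyer", "rice",
    "schmidt", "garza", "daniels", "ferguson", "nichols", "stephens",
    "soto", "weaver", "ryan", "gardner", "payne", "grant", "dunn", "kelley",
    "spencer", "hawkins", "arnold", "pierce", "vazquez", "hansen", "peters",
    "santos", "hart", "bradley", "knight", "elliott", "cunningham",
    "duncan", "armstrong", "hudson", "carroll", "lane", "riley", "andrews",
    "alvarado", "ray", "delgado", "berry", "perkins", "hoffman", "johnston",
    "matthews", "pena", "richards", "contreras", "willis", "carpenter",
    "lawrence", "sandoval", "guerrero", "george", "chapman", "rios",
    "estrada", "ortega", "watkins", "greene", "nunez", "wheeler", "valdez",
    "harper", "burke", "larson", "santiago", "maldonado", "morrison",
    "franklin", "carlson", "austin", "dominguez", "carr", "lawson",
    "jacobs", "obrien", "lynch", "singh", "vega", "bishop", "montgomery",
    "oliver", "jensen", "harvey", "williamson", "gilbert", "dean", "sims",
    "espinoza", "howell", "li", "wong", "reid", "hanson", "le", "mccoy",
    "garrett", "burton", "fuller", "wang", "weber", "welch", "rojas",
]

STREET_NAMES = [
    "maple", "oak", "elm", "cedar", "pine", "walnut", "willow", "chestnut",
    "spruce", "birch", "college", "allen", "beaver", "atherton", "pugh",
    "fraser", "garner", "hamilton", "foster", "nittany", "curtin", "fairmount",
    "hiester", "sparks", "burrowes", "mckee", "holmes", "ridge", "sunset",
    "park", "hillcrest", "prospect", "adams", "washington", "franklin",
]
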