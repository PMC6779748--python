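# Open mini-lexicon for dictionary-based psycholinguistic counting.
# Format: category: entry, entry, ...   ('*' = prefix wildcard, entry-final only)
# Small open word lists in the spirit of closed-class dictionary schemes;
# users may substitute a full licensed dictionary in the same format.

first_person_singular: i, me, my, mine, myself, i'm, i've, i'll, i'd, im
first_person_plural: we, us, our, ours, ourselves, we're, we've, we'll, we'd, lets, let's
second_person: you, your, yours, yourself, yourselves, you're, you've, you'll, you'd, u, ur, y'all
indefinite_pronoun: it, its, this, that, these, those, something, anything, nothing, somebody, anybody, nobody, someone, anyone, everyone, everything, stuff
quantifier: all, lot, lots, few, many, much, more, most, some, several, bunch, plenty, every, each, double, single
negation: no, not, never, none, cannot, can't, don't, won't, didn't, isn't, aren't, wasn't, weren't, neither, nor, without
verbs: is, am, are, was, were, be, been, being, has, have, had, do, does, did, go, goes, going, went, gone, get, gets, getting, got, make, makes, making, made, say, says, said, come, comes, came
future_tense: will, shall, gonna, won't, i'll, we'll, you'll, they'll, she'll, he'll, tomorrow, soon
swear: damn*, dammit, shit*, fuck*, bitch*, crap*, ass, asses, asshole*, bastard*, piss*, bullshit*
anger: hate*, hating, kill*, angry, anger, mad, madder, rage*, furious, fight*, fought, attack*, hostil*, resent*, annoy*, jealous*, outrage*, jerk
negative_affect: bad, hurt*, awful, terrible, worthless, ugly, nasty, guilt*, horribl*, miser*, lousy, gross, disappoint*
anxiety: anxious*, anxiety, nervous*, worr*, afraid, fear*, scare*, scaring, panic*, stress*, tense, uneasy, dread*, overwhelm*
sadness: sad, sadness, depress*, cry*, crying, cried, grief*, griev*, sorrow*, lonel*, gloom*, hopeless*, heartbroken
death: dead, death*, die, died, dies, dying, kill*, suicid*, funeral*, grave*, bury*, buried, coffin*, fatal*, overdose*
hear: hear, heard, hearing, hears, listen*, sound*, voice*, noise*, loud, louder, music, song*, audio
feel: feel, feels, feeling*, felt, touch*, soft, softer, rough, smooth, warm, warmer, numb*, itch*, ache*
bio: eat*, ate, sleep*, slept, blood*, pain*, pills, pill, drug*, meds, medicat*, breath*, stomach*, dizzy, tired, hungry, thirsty
body: body, bodies, arm, arms, leg, legs, head, heads, hand, hands, face, faces, eye, eyes, hair, skin, heart*, teeth, tooth, mouth, shoulder*, knee*, foot, feet
health: health*, sick*, ill, illness*, doctor*, hospital*, nurse*, clinic*, therap*, symptom*, diagnos*, flu, fever*, injur*, recover*, appointment*
sexual: sex*, lust*, kiss*, naked*, horny, porn*, hookup*, flirt*, crush, crushes
family: family, families, mom, moms, mommy, mother*, dad, dads, daddy, father*, brother*, sister*, son, sons, daughter*, grandm*, grandp*, aunt*, uncle*, cousin*, wife, husband*, parent*
friends: friend*, buddy, buddies, pal, pals, neighbor*, roommate*, bff, bro, bros, dude*, homie*, mate, mates
humans: people, person*, human*, man, men, woman*, women, guy*, girl*, boy*, kid*, child*, children, adult*, folk*, stranger*
work: work*, job*, boss*, office*, school*, class, classes, college*, homework*, career*, employ*, intern*, salary*, shift, shifts, meeting*, resume*, hired, hiring, fired
achievement: achiev*, accomplish*, success*, win, wins, winning, won, earn*, effort*, goal*, master*, improve*, proud*, award*, promot*, graduat*
money: money, cash, paid, pay*, buy*, bought, cost*, price*, dollar*, bank*, rent, loan*, debt*, rich*, broke, cheap*, bills
religion: god*, pray*, church*, bible*, faith*, holy, jesus*, allah, heaven*, sacred*, worship*, spirit*, amen, bless*, sin, sins
home: home*, house*, apartment*, kitchen*, bedroom*, bed, beds, couch*, yard*, garage*, laundry*, porch*, landlord*
insight: think*, thought*, know, knows, knew, known, realiz*, understand*, understood, believ*, aware*, decid*, reflect*, reason*, figur*
causation: because, cause*, caused, causing, effect*, hence, therefore, thus, since, depend*, result*, force*, why, bc, cuz
discrepancies: should, would, could, ought, hope*, wish*, want*, need*, lack*, prefer*, if, regret*, shoulda, woulda, coulda
tentativeness: maybe, perhaps, guess*, kinda, sorta, somewhat, possib*, probabl*, might, seem, seems, seemed, unsure, unclear, idk, dunno
certainty: always, definitely, certain*, sure, surely, absolutely, clearly, completely, totally, truly, undoubtedly, obvious*, must
inhibition: stop*, stopped, stopping, block*, constrain*, avoid*, careful*, hold, holds, held, control*, restrain*, prevent*, wait*, quit*, ban, bans, banned
inclusive: with, and, along, together, both, include*, including, plus, add*, join*, share, shared, sharing
exclusive: but, except, without, exclude*, however, although, though, either, versus, unless
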