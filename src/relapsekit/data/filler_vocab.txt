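# 200 neutral filler words (verified not to match any mini-lexicon category)
the a an of to in on at for from
by as about into over under after before during between
around near above below across behind beyond outside inside today
yesterday morning evening afternoon week month year hour minute moment
time day night light dark blue green red yellow orange
purple white black grey coffee tea water juice bread rice
pasta pizza salad soup cheese apple banana grape lemon mango
berry melon chicken beef fish egg milk sugar salt pepper
butter honey table chair desk lamp window door wall floor
ceiling roof street road bridge park river lake ocean beach
mountain hill forest tree leaf flower grass stone rock sand
cloud rain snow wind storm sun moon star sky train
bus car bike plane boat ship station airport ticket map
trip travel walk ran run jog swim dance sing read
write draw photo camera movie film show episode game match
ball team score coach player book page chapter story poem
letter word sentence paper pen pencil marker phone laptop screen
keyboard mouse cable charger battery signal wifi site link post
tweet message email chat call text note list plan idea
city town village country state region area place spot corner
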